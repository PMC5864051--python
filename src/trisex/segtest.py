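"""Chi-squared goodness-of-fit of sex-class counts against segregation ratios.

Marker class dictates both the pooling of phenotype counts and the expected
ratio: a three-sex marker separates F:H:M at 1:1:1, a female-type marker
separates F from the pooled M+H at 1:2, and a male-type marker separates the
pooled F+H from M at 2:1 (the hermaphrodite x male cross with Y/Y lethality).
The statistic is the uncorrected Pearson chi-square; no Yates correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from scipy.stats import chi2 as _chi2_dist

from .synthio import MarkerClass

ALPHA = 0.05
# critical values at alpha = 0.05 for the degrees of freedom the assay uses
CRITICAL_VALUES = {1: 3.841, 2: 5.991}


@dataclass(frozen=True)
class SegregationObservation:
    labels: tuple[str, ...]
    observed: tuple[int, ...]
    ratio: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.labels) == len(self.observed) == len(self.ratio) >= 2):
            raise ValueError("need >= 2 matching classes, counts and ratio terms")
        if any(o < 0 or o != int(o) for o in self.observed):
            raise ValueError("observed counts must be non-negative integers")
        if sum(self.observed) < 1:
            raise ValueError("total observed count must be >= 1")
        if any(r < 1 or r != int(r) for r in self.ratio):
            raise ValueError("ratio terms must be positive integers")


@dataclass(frozen=True)
class SegregationResult:
    chi2: float
    chi2_rounded: float  # half-up to 2 decimals, for display
    df: int
    expected: tuple[float, ...]
    p_value: float
    significant: bool  # chi2 above the alpha = 0.05 critical value


def pool_counts(counts: Mapping[str, int], marker_class: MarkerClass) -> SegregationObservation:
    """Pool per-sex counts according to what the marker can distinguish."""
    f, h, m = (int(counts.get(s, 0)) for s in ("F", "H", "M"))
    if marker_class == MarkerClass.THREE_SEX:
        return SegregationObservation(("F", "H", "M"), (f, h, m), (1, 1, 1))
    if marker_class == MarkerClass.FEMALE_TYPE:
        return SegregationObservation(("F", "M+H"), (f, m + h), (1, 2))
    if marker_class == MarkerClass.MALE_TYPE:
        return SegregationObservation(("F+H", "M"), (f + h, m), (2, 1))
    raise ValueError(f"unknown marker class {marker_class!r}")


def round_half_up(x: float, digits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -digits, rounding=ROUND_HALF_UP))


def chi_square_gof(obs: SegregationObservation) -> SegregationResult:
    """Pearson chi-square against expected counts E_i = N * r_i / sum(r)."""
    total = sum(obs.observed)
    rsum = sum(obs.ratio)
    expected = tuple(total * r / rsum for r in obs.ratio)
    if any(e == 0 for e in expected):
        raise ValueError("expected count of zero")
    stat = sum((o - e) ** 2 / e for o, e in zip(obs.observed, expected))
    df = len(obs.observed) - 1
    critical = CRITICAL_VALUES.get(df, float(_chi2_dist.isf(ALPHA, df)))
    return SegregationResult(
        chi2=stat,
        chi2_rounded=round_half_up(stat),
        df=df,
        expected=expected,
        p_value=float(_chi2_dist.sf(stat, df)),
        significant=stat > critical,
    )


def segregation_report(
    counts_by_marker: Mapping[str, Mapping[str, int]],
    class_by_marker: Mapping[str, MarkerClass],
):
    """Tabular report (marker, pooled counts, ratio, chi2, df, significance)."""
    import pandas as pd

    rows = []
    for marker in sorted(counts_by_marker):
        obs = pool_counts(counts_by_marker[marker], class_by_marker[marker])
        res = chi_square_gof(obs)
        rows.append(
            {
                "marker": marker,
                "observed": " ".join(f"{l}={o}" for l, o in zip(obs.labels, obs.observed)),
                "ratio": ":".join(str(r) for r in obs.ratio),
                "chi2": res.chi2_rounded,
                "df": res.df,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def calibration_rejection_rate(
    ratio: Sequence[int],
    n: int = 96,
    replicates: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the test under a true multinomial null."""
    import numpy as np

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = np.asarray(ratio, dtype=float)
    p /= p.sum()
    counts = rng.multinomial(n, p, size=replicates)
    expected = n * p
    stats = ((counts - expected) ** 2 / expected).sum(axis=1)
    df = len(ratio) - 1
    critical = CRITICAL_VALUES.get(df, float(_chi2_dist.isf(ALPHA, df)))
    return float(np.mean(stats > critical))
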