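"""In-silico marker assays: PCR, restriction digestion, junction RT-PCR and HRM.

PCR uses exact primer matching (the assays are presence/absence); digestion
covers the two enzymes the screen uses (NdeI CA^TATG, SpeI A^CTAGT), with the
table extensible.  Melt curves follow a two-state logistic proxy per allele -
heterozygotes are an equal mixture of the two homoduplex curves plus two
heteroduplex curves shifted down in Tm - normalised against linear baselines
at the grid ends and clustered by nearest reference-seeded centroid on the
maximum absolute difference between difference curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthio import GeneModel, MarkerDef, SexGenotype

MIN_PRIMER_LEN = 15
MAX_AMPLICON_LEN = 5000
DEFAULT_CLUSTER_THRESHOLD = 0.05

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers (5'->3'); junction primers record (exon i, a, b):
    the forward spans the last ``a`` bases of exon i and first ``b`` of exon i+1."""

    name: str
    forward: str
    reverse: str
    junction: tuple[int, int, int] | None = None

    def __post_init__(self):
        if len(self.forward) < MIN_PRIMER_LEN or len(self.reverse) < MIN_PRIMER_LEN:
            raise ValueError("primers must be >= 15 nt")


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int  # half-open, template coordinates
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError("amplicon sequence must equal the template slice")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RestrictionDigest:
    enzyme: str
    recognition: str
    fragments: tuple[int, ...]  # bp, ordered along the amplicon


def _find_all(template: str, pattern: str) -> list[int]:
    out, i = [], template.find(pattern)
    while i >= 0:
        out.append(i)
        i = template.find(pattern, i + 1)
    return out


def in_silico_pcr(
    template: str,
    primers: PrimerPair,
    max_products: int = 10,
    template_id: str = "template",
) -> list[Amplicon]:
    """Exact-match PCR: forward on the plus strand, reverse-complemented
    reverse primer downstream; products longer than 5 kb never amplify.

    Returns all valid pairings, shortest (nearest pairing) first; an empty
    list models the absence of a PCR product.
    """
    fwd_sites = _find_all(template, primers.forward)
    rev_sites = _find_all(template, revcomp(primers.reverse))
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(primers.reverse)
            if r < f + len(primers.forward):
                continue
            if end - f > MAX_AMPLICON_LEN:
                continue
            products.append(Amplicon(template_id, f, end, template[f:end]))
    products.sort(key=lambda a: (a.length, a.start))
    return products[:max_products]


# enzyme table: recognition sequence and cut offset on the top strand
ENZYMES: dict[str, tuple[str, int]] = {
    "NdeI": ("CATATG", 2),  # CA^TATG
    "SpeI": ("ACTAGT", 1),  # A^CTAGT
}


def digest(amplicon: Amplicon, enzyme: str,
           enzymes: Mapping[str, tuple[str, int]] = ENZYMES) -> RestrictionDigest:
    """Cut at every non-overlapping recognition occurrence, left to right.

    With no site the single fragment equals the amplicon; fragment lengths
    always sum to the amplicon length.
    """
    if enzyme not in enzymes:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    site, offset = enzymes[enzyme]
    seq = amplicon.sequence
    cuts, i = [], seq.find(site)
    while i >= 0:
        cuts.append(i + offset)
        i = seq.find(site, i + len(site))
    bounds = [0] + cuts + [len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return RestrictionDigest(enzyme, site, fragments)


# ---------------------------------------------------------------------------
# junction RT-PCR
# ---------------------------------------------------------------------------

def design_junction_primers(
    model: GeneModel, reference: str, a: int = 10, b: int = 10,
    rev_len: int = 20, rev_gap: int = 5,
) -> dict[int, tuple[PrimerPair, int]]:
    """One junction-spanning primer pair per intron of the model.

    The forward primer covers the last ``a`` bases of exon i and the first
    ``b`` bases of exon i+1, so a retained intron i abolishes its product;
    the reverse primer sits ``rev_gap`` bases further into exon i+1.  Returns
    {intron index: (pair, expected product length on the spliced transcript)}.
    """
    spliced = model.spliced_sequence(reference)
    out: dict[int, tuple[PrimerPair, int]] = {}
    for i, j in enumerate(model.junction_positions()):
        if j - a < 0 or j + b + rev_gap + rev_len > len(spliced):
            continue
        nxt_len = model.exon_lengths[i + 1]
        if nxt_len < b + rev_gap + rev_len:
            continue
        fwd = spliced[j - a : j + b]
        r0 = j + b + rev_gap
        rev = revcomp(spliced[r0 : r0 + rev_len])
        pair = PrimerPair(f"{model.gene_id}_jx{i + 1}", fwd, rev, junction=(i, a, b))
        out[i] = (pair, a + b + rev_gap + rev_len)
    return out


def junction_products(
    transcript: str, primers: Mapping[int, tuple[PrimerPair, int]]
) -> dict[int, int | None]:
    """Observed product length per junction assay (None = no product)."""
    obs: dict[int, int | None] = {}
    for i, (pair, _expected) in sorted(primers.items()):
        products = in_silico_pcr(transcript, pair)
        obs[i] = products[0].length if products else None
    return obs


# ---------------------------------------------------------------------------
# HRM melt simulation, normalisation, clustering
# ---------------------------------------------------------------------------

@dataclass
class MeltCurve:
    temperature: np.ndarray  # deg C, ascending uniform grid
    fluorescence: np.ndarray
    sample_id: str = ""
    marker: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("one fluorescence value per grid point required")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    marker: str
    cluster: str
    concordant_with_sex: bool | None = None


def default_grid(start: float = 65.0, stop: float = 90.0, step: float = 0.2) -> np.ndarray:
    return np.round(np.arange(start, stop + step / 2, step), 6)


def _logistic(temp: np.ndarray, tm: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((temp - tm) / slope))


def simulate_melt(
    allele_pair: Sequence[str],
    tm_by_allele: Mapping[str, float],
    slope: float = 0.5,
    het_delta_tm: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    grid: np.ndarray | None = None,
    sample_id: str = "",
    marker: str = "",
) -> MeltCurve:
    """Two-state logistic melt proxy.

    Homozygotes melt as a single logistic around their allele Tm; a
    heterozygote is the equal mixture of both homoduplex curves and two
    heteroduplex curves at Tm - het_delta_tm.  Gaussian noise is added per
    grid point; deterministic under a fixed seed.
    """
    temp = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if temp.size < 2 or np.any(np.diff(temp) <= 0):
        raise ValueError("temperature grid must be ascending")
    a, b = allele_pair
    tma, tmb = tm_by_allele[a], tm_by_allele[b]
    for tm in (tma, tmb):
        if not 70.0 < tm < 88.0:
            raise ValueError(f"Tm {tm} outside the supported (70, 88) range")
    if a == b:
        fl = _logistic(temp, tma, slope)
    else:
        fl = (
            _logistic(temp, tma, slope)
            + _logistic(temp, tmb, slope)
            + _logistic(temp, tma - het_delta_tm, slope)
            + _logistic(temp, tmb - het_delta_tm, slope)
        ) / 4.0
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        fl = fl + rng.normal(0.0, noise_sd, temp.size)
    return MeltCurve(temp, fl, sample_id=sample_id, marker=marker)


def normalize_melt(
    curve: MeltCurve,
    pre_window: tuple[float, float] = (65.0, 68.0),
    post_window: tuple[float, float] = (87.0, 90.0),
) -> MeltCurve:
    """Two-baseline normalisation: fit a line in each end window and rescale
    to (F - post) / (pre - post), clipped to [-0.05, 1.05].

    Each baseline is the fitted line's level at its window centre.  The melt
    proxy's plateaus are flat, so extrapolating the fitted lines across the
    grid would only amplify measurement noise far from the windows.
    """
    t, f = curve.temperature, curve.fluorescence
    pre_mask = (t >= pre_window[0]) & (t <= pre_window[1])
    post_mask = (t >= post_window[0]) & (t <= post_window[1])
    for mask, name in ((pre_mask, "pre"), (post_mask, "post")):
        if mask.sum() < 3:
            raise ValueError(f"{name} window must contain >= 3 grid points")
    pre_fit = np.polyfit(t[pre_mask], f[pre_mask], 1)
    post_fit = np.polyfit(t[post_mask], f[post_mask], 1)
    pre = float(np.polyval(pre_fit, t[pre_mask].mean()))
    post = float(np.polyval(post_fit, t[post_mask].mean()))
    span = pre - post
    if abs(span) < 1e-9:
        raise ValueError("degenerate (flat) curve: pre and post baselines coincide")
    norm = np.clip((f - post) / span, -0.05, 1.05)
    return MeltCurve(t, norm, sample_id=curve.sample_id, marker=curve.marker)


@dataclass
class ClusterResult:
    calls: list[GenotypeCall]
    correlation_pct: dict[str, float]  # per reference label
    blind_counts: dict[str, int]  # non-reference samples per cluster


def cluster_melt(
    curves: Sequence[MeltCurve],
    reference: Mapping[str, str],  # sample_id -> known cluster label
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> ClusterResult:
    """Assign each curve to the nearest reference-seeded centroid.

    Distance is the maximum absolute pointwise difference between a sample's
    curve and the cluster centroid (the difference-curve criterion); samples
    further than ``threshold`` from every centroid become singletons.
    Correlation % per label is the fraction of that label's reference samples
    assigned to their own cluster; blind (non-reference) samples are counted
    per cluster for downstream segregation testing.
    """
    if not reference:
        raise ValueError("at least one reference sample per expected cluster required")
    by_id = {c.sample_id: c for c in curves}
    missing = [sid for sid in reference if sid not in by_id]
    if missing:
        raise ValueError(f"reference samples missing from curves: {missing}")
    labels = sorted(set(reference.values()))
    centroids = {}
    for lab in labels:
        members = [by_id[sid].fluorescence for sid, l in sorted(reference.items()) if l == lab]
        centroids[lab] = np.mean(members, axis=0)

    calls = []
    assigned: dict[str, str] = {}
    for c in sorted(curves, key=lambda c: c.sample_id):
        dists = {lab: float(np.max(np.abs(c.fluorescence - cen)))
                 for lab, cen in centroids.items()}
        lab = min(dists, key=lambda l: (dists[l], l))
        if dists[lab] >= threshold:
            lab = f"singleton:{c.sample_id}"
        assigned[c.sample_id] = lab
        calls.append(GenotypeCall(c.sample_id, c.marker, lab))

    correlation = {}
    for lab in labels:
        ref_ids = [sid for sid, l in reference.items() if l == lab]
        hit = sum(assigned[sid] == lab for sid in ref_ids)
        correlation[lab] = 100.0 * hit / len(ref_ids)
    blind: dict[str, int] = {}
    for sid, lab in assigned.items():
        if sid not in reference:
            blind[lab] = blind.get(lab, 0) + 1
    return ClusterResult(calls, correlation, blind)


# ---------------------------------------------------------------------------
# marker-level helpers tying HRM to the genetic model
# ---------------------------------------------------------------------------

def marker_cluster_label(marker: MarkerDef, genotype: SexGenotype) -> str:
    """Expected cluster label of a genotype at a marker: genotypes whose
    allele pairs coincide share a pooled label (e.g. 'M+H' at a female-type
    marker where the Ym and Yh alleles are identical)."""
    from .synthio import GENOTYPE_BY_LABEL

    pair = marker.allele_pair(genotype)
    same = sorted(
        {"XX": "F", "XYm": "M", "XYh": "H"}[lab]
        for lab, g in GENOTYPE_BY_LABEL.items()
        if marker.allele_pair(g) == pair
    )
    return "+".join(same)


def simulate_marker_hrm(
    marker: MarkerDef,
    progeny: pd.DataFrame,
    noise_sd: float = 0.01,
    seed: int = 0,
    slope: float = 0.5,
    het_delta_tm: float = 1.0,
    n_reference_per_class: int = 4,
) -> tuple[list[MeltCurve], dict[str, str], pd.DataFrame]:
    """Simulate normalised melt curves for a progeny table at one marker.

    The first ``n_reference_per_class`` samples of each expected cluster act
    as known-sex reference samples (the study's identified parents/progeny).
    Returns (normalised curves, reference assignment, truth table).
    """
    from .synthio import GENOTYPE_BY_LABEL

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    curves, rows = [], []
    ref_assign: dict[str, str] = {}
    ref_counts: dict[str, int] = {}
    for _, row in progeny.iterrows():
        genotype = GENOTYPE_BY_LABEL[row["genotype"]]
        pair = marker.allele_pair(genotype)
        label = marker_cluster_label(marker, genotype)
        curve = simulate_melt(
            pair, marker.tm, slope=slope, het_delta_tm=het_delta_tm,
            noise_sd=noise_sd, seed=rng, sample_id=row["sample_id"],
            marker=marker.name,
        )
        curves.append(normalize_melt(curve))
        if ref_counts.get(label, 0) < n_reference_per_class:
            ref_assign[row["sample_id"]] = label
            ref_counts[label] = ref_counts.get(label, 0) + 1
        rows.append({"sample_id": row["sample_id"], "true_cluster": label,
                     "phenotype": row["phenotype"]})
    return curves, ref_assign, pd.DataFrame(rows)


def melt_curves_frame(curves: Iterable[MeltCurve]) -> pd.DataFrame:
    """Long-format table (sample_id, marker, temperature, fluorescence)."""
    rows = []
    for c in curves:
        for t, f in zip(c.temperature, c.fluorescence):
            rows.append({"sample_id": c.sample_id, "marker": c.marker,
                         "temperature": t, "fluorescence": f})
    return pd.DataFrame(rows)
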