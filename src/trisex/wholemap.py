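"""Integrate per-locus expression class, AS flag and genotype into flower-type calls.

The functional map summarises each floral whorl by a triple per locus -
(expression class, alternative-splicing flag, sex-chromosome genotype) - at
the three canonical loci CpSERK, CpSVPL and CpCAF1AL.  A small data-driven
rule table maps third-whorl profiles to male (M), normal hermaphrodite (H),
female-sterile (HM) and carpellate (HF) flowers, and a fourth-whorl profile
to females; a hermaphrodite call is additionally checked for the stable-
hermaphrodite marker combination.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import markerlab
from .synthio import FlowerCohort

LOCI = ("CpSERK", "CpSVPL", "CpCAF1AL")


class ExpressionClass(str, enum.Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    NOVAR = "NOVAR"


class AsFlag(str, enum.Enum):
    AS = "AS"
    NO_AS = "NO_AS"


@dataclass(frozen=True)
class LocusState:
    expression: ExpressionClass
    splicing: AsFlag
    genotype: str  # XX / XYm / XYh


LocusProfile = Mapping[str, LocusState]


@dataclass(frozen=True)
class FlowerTypeCall:
    predicted: str  # M, H, HM, HF, F_fourth_whorl or UNKNOWN
    rule_id: str | None
    stable_hermaphrodite: bool | None = None


def classify_expression(
    value: float,
    panel: Sequence[float],
    high_fold: float = 2.0,
    low_fold: float = 0.5,
) -> ExpressionClass:
    """HIGH / LOW / NOVAR relative to the panel median.

    The panel should include baseline tissue (whole-bud) measurements so its
    median anchors at the unshifted level; thresholds are fold-changes.
    """
    panel = np.asarray(panel, dtype=float)
    if panel.size < 3:
        raise ValueError("panel median needs >= 3 samples")
    med = float(np.median(panel))
    if med == 0.0:
        raise ValueError("all-zero expression panel")
    if value >= high_fold * med:
        return ExpressionClass.HIGH
    if value <= low_fold * med:
        return ExpressionClass.LOW
    return ExpressionClass.NOVAR


def derive_as_flag(
    observed: Mapping[int, int | None],
    expected: Mapping[int, int],
    length_tolerance: int = 5,
) -> AsFlag:
    """AS if any junction assay fails or returns an off-length product."""
    if not expected:
        raise ValueError("no junction assays defined for this locus")
    for junction, exp_len in expected.items():
        obs = observed.get(junction)
        if obs is None or abs(obs - exp_len) > length_tolerance:
            return AsFlag.AS
    return AsFlag.NO_AS


# Rule table is data, not code: each rule constrains (expression, AS) per
# locus (null = wildcard), the genotype at every locus, and the whorl.
DEFAULT_RULES: list[dict] = [
    {"id": "M", "whorl": "third", "genotype": "XYm", "predict": "M",
     "CpSERK": ["NOVAR", "NO_AS"], "CpSVPL": ["HIGH", "NO_AS"],
     "CpCAF1AL": ["HIGH", "NO_AS"]},
    {"id": "H", "whorl": "third", "genotype": "XYh", "predict": "H",
     "CpSERK": ["NOVAR", "NO_AS"], "CpSVPL": ["LOW", "NO_AS"],
     "CpCAF1AL": ["HIGH", "NO_AS"]},
    {"id": "HM", "whorl": "third", "genotype": "XYh", "predict": "HM",
     "CpSERK": ["NOVAR", "AS"], "CpSVPL": ["HIGH", "NO_AS"],
     "CpCAF1AL": ["LOW", "AS"]},
    {"id": "HF", "whorl": "third", "genotype": "XYh", "predict": "HF",
     "CpSERK": ["NOVAR", "AS"], "CpSVPL": ["LOW", "NO_AS"],
     "CpCAF1AL": ["LOW", "AS"]},
    {"id": "F4W", "whorl": "fourth", "genotype": "XX", "predict": "F_fourth_whorl",
     "CpSERK": [None, "AS"], "CpSVPL": ["LOW", "NO_AS"],
     "CpCAF1AL": ["LOW", "AS"]},
]


def load_rule_table(path: str) -> list[dict]:
    """Load a custom rule table (same schema as DEFAULT_RULES) from YAML."""
    with open(path) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, list):
        raise ValueError("rule table must be a list of rules")
    return rules


def _rule_matches(rule: dict, profile: LocusProfile, whorl: str) -> bool:
    if rule["whorl"] != whorl:
        return False
    for locus in LOCI:
        state = profile[locus]
        want_expr, want_as = rule[locus]
        if want_expr is not None and state.expression != ExpressionClass(want_expr):
            return False
        if want_as is not None and state.splicing != AsFlag(want_as):
            return False
        if state.genotype != rule["genotype"]:
            return False
    return True


def predict_flower_type(
    profile: LocusProfile, whorl: str, rules: Sequence[dict] = DEFAULT_RULES
) -> FlowerTypeCall:
    """Match the locus profile against the rule table; UNKNOWN if nothing fits."""
    missing = [l for l in LOCI if l not in profile]
    if missing:
        raise ValueError(f"profile incomplete, missing loci: {missing}")
    for rule in rules:
        if _rule_matches(rule, profile, whorl):
            return FlowerTypeCall(rule["predict"], rule["id"])
    return FlowerTypeCall("UNKNOWN", None)


def call_stable_hermaphrodite(
    call: FlowerTypeCall, marker_genotypes: Mapping[str, str]
) -> bool:
    """Stable-hermaphrodite check for a predicted normal hermaphrodite.

    True iff the CpSERK locus lacks the female (XX) genotype, CpSVPL carries
    the XYh genotype, and CpCAF1AL lacks the male (XYm) genotype.
    """
    if call.predicted != "H":
        raise ValueError("stable-hermaphrodite flag is defined only for H calls")
    return (
        marker_genotypes["CpSERK"] != "XX"
        and marker_genotypes["CpSVPL"] == "XYh"
        and marker_genotypes["CpCAF1AL"] != "XYm"
    )


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def map_flower_cohort(
    cohort: FlowerCohort, rules: Sequence[dict] = DEFAULT_RULES
) -> pd.DataFrame:
    """End-to-end functional mapping of a generated flower cohort.

    Expression classes come from the per-locus panel (whorl plus whole-bud
    baseline measurements); AS flags from junction RT-PCR on each sample's
    cDNA; genotypes from the sample's marker genotype.  Returns one row per
    sample with the predicted flower type and, for H calls, the stable flag.
    """
    primers = {
        locus: markerlab.design_junction_primers(kit.model, kit.reference)
        for locus, kit in cohort.loci.items()
    }
    expected = {
        locus: {i: exp_len for i, (_pair, exp_len) in jx.items()}
        for locus, jx in primers.items()
    }
    panels = {
        locus: cohort.expression.loc[cohort.expression["locus"] == locus, "value"].to_numpy()
        for locus in cohort.loci
    }
    expr_lookup = {
        (r.sample_id, r.locus, r.whorl): r.value
        for r in cohort.expression.itertuples()
    }

    rows = []
    for sample in cohort.samples.itertuples():
        profile = {}
        for locus in LOCI:
            value = expr_lookup[(sample.sample_id, locus, sample.whorl)]
            expr_class = classify_expression(value, panels[locus])
            obs = markerlab.junction_products(
                cohort.transcripts[(sample.sample_id, locus)], primers[locus]
            )
            as_flag = derive_as_flag(obs, expected[locus])
            profile[locus] = LocusState(expr_class, as_flag, sample.genotype)
        call = predict_flower_type(profile, sample.whorl, rules)
        stable = None
        if call.predicted == "H":
            stable = call_stable_hermaphrodite(
                call, {locus: profile[locus].genotype for locus in LOCI}
            )
        rows.append(
            {
                "sample_id": sample.sample_id,
                "true_class": sample.true_class,
                "whorl": sample.whorl,
                "predicted": call.predicted,
                "rule_id": call.rule_id,
                "stable_hermaphrodite": stable,
            }
        )
    return pd.DataFrame(rows)


def prediction_accuracy(mapped: pd.DataFrame) -> float:
    """Fraction of cohort samples whose prediction matches the planted class
    (females are profiled in the fourth whorl, hence the F label mapping)."""
    truth_to_label = {"M": "M", "H": "H", "HM": "HM", "HF": "HF", "F": "F_fourth_whorl"}
    want = mapped["true_class"].map(truth_to_label)
    return float((mapped["predicted"] == want).mean())
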