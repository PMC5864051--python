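"""Splice-event calling and sex-grouping of genes across the three sex types.

Each sex type's representative transcript is globally aligned to its gene
model's spliced (exon-chain) sequence with affine gap scores.  Insertions
matching an annotated intron (within +/-2 bp) are intron retentions,
deletions matching an annotated exon are exon skips, and premature stop
codons found by CDS translation are truncations.  Per gene the four-way
category (exon jump > intron jump > AA short > no change) and the
presence/amino-acid sex-grouping (type_1 / type_2 / type_3) are derived.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .synthio import CORE_SEXES, Dataset, EventType, GeneModel

EVENT_BOUNDARY_SLACK = 2  # bp of alignment ambiguity absorbed at event edges
MIN_MODEL_IDENTITY = 0.95  # over aligned (non-gap) columns


class AsCategory(str, enum.Enum):
    EXON_JUMP = "EXON_JUMP"
    INTRON_JUMP = "INTRON_JUMP"
    AA_SHORT = "AA_SHORT"
    NO_CHANGE = "NO_CHANGE"


class SexGroupType(str, enum.Enum):
    TYPE_1 = "TYPE_1"
    TYPE_2 = "TYPE_2"
    TYPE_3 = "TYPE_3"
    NONE = "NONE"


@dataclass(frozen=True)
class SpliceEvent:
    """One detected difference between a transcript and its gene model."""

    kind: EventType
    index: int  # intron/exon index, or spliced position for substitutions
    detail: str = ""


@dataclass(frozen=True)
class Translation:
    aa: str  # translation up to (not including) the first stop
    first_stop: int | None  # codon index of the first stop, if any
    truncated: bool  # stop observed before the annotated CDS end
    frameshift: bool  # mapped CDS length not divisible by 3


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2
    al.mismatch_score = -3
    al.open_gap_score = -6
    al.extend_gap_score = -1
    return al


@dataclass
class _ModelAlignment:
    """Parsed global alignment of a transcript (query) to the spliced model (target)."""

    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    mismatches: tuple[tuple[int, str, str], ...]  # (target pos, ref, alt)
    insertions: tuple[tuple[int, str], ...]  # (target pos, inserted query seq)
    deletions: tuple[tuple[int, int], ...]  # (target start, target end)
    identity: float  # matches / aligned columns

    def map_target_pos(self, p: int) -> int:
        """Map a spliced-model position to the transcript coordinate."""
        for (ts, te), (qs, _qe) in self.blocks:
            if ts <= p < te:
                return qs + (p - ts)
        # position falls in a deletion: map to the query position at its edge
        for (ts, te), (qs, _qe) in self.blocks:
            if p < ts:
                return qs
        return self.blocks[-1][1][1]


def _align_to_spliced(transcript: str, spliced: str) -> _ModelAlignment:
    aln = _aligner().align(spliced, transcript)[0]
    t_blocks, q_blocks = aln.aligned
    blocks = tuple(
        ((int(ts), int(te)), (int(qs), int(qe)))
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
    )
    mismatches, insertions, deletions = [], [], []
    matches = cols = 0
    prev_t = prev_q = 0
    first = True
    for (ts, te), (qs, qe) in blocks:
        if not first or ts > 0 or qs > 0:
            dt, dq = ts - prev_t, qs - prev_q
            if dq > 0:
                insertions.append((prev_t, transcript[prev_q : prev_q + dq]))
            if dt > 0:
                deletions.append((prev_t, ts))
        first = False
        for i in range(te - ts):
            a, b = spliced[ts + i], transcript[qs + i]
            cols += 1
            if a == b:
                matches += 1
            else:
                mismatches.append((ts + i, a, b))
        prev_t, prev_q = te, qe
    if prev_t < len(spliced):
        deletions.append((prev_t, len(spliced)))
    if prev_q < len(transcript):
        insertions.append((len(spliced), transcript[prev_q:]))
    identity = matches / cols if cols else 0.0
    return _ModelAlignment(blocks, tuple(mismatches), tuple(insertions),
                           tuple(deletions), identity)


def align_to_model(
    transcript: str, model: GeneModel, reference: str
) -> list[SpliceEvent]:
    """Call splice/substitution events for one transcript against its model.

    Raises ``ValueError`` when the transcript does not belong to the model
    (aligned-column identity below the mapping threshold).
    """
    spliced = model.spliced_sequence(reference)
    aln = _align_to_spliced(transcript, spliced)
    if aln.identity < MIN_MODEL_IDENTITY:
        raise ValueError(
            f"transcript/model mismatch for {model.gene_id}: "
            f"identity {aln.identity:.3f} < {MIN_MODEL_IDENTITY}"
        )
    events: list[SpliceEvent] = []
    junctions = model.junction_positions()
    introns = model.intron_sequences(reference)
    offsets = model.exon_spliced_offsets
    lengths = model.exon_lengths

    for pos, ins in aln.insertions:
        matched = None
        for i, j in enumerate(junctions):
            if len(ins) == len(introns[i]) and (
                spliced[:pos] + ins + spliced[pos:]
                == spliced[:j] + introns[i] + spliced[j:]
            ):
                # tie: the aligner may slide a gap off the splice site when
                # boundary bases repeat; equivalence resolves toward the
                # annotated junction
                matched = i
                break
            if (
                abs(pos - j) <= EVENT_BOUNDARY_SLACK
                and abs(len(ins) - len(introns[i])) <= EVENT_BOUNDARY_SLACK
                and _approx_equal(ins, introns[i])
            ):
                matched = i
                break
        if matched is not None:
            events.append(SpliceEvent(EventType.INTRON_RETENTION, matched))
        else:
            events.append(
                SpliceEvent(EventType.SNP, pos, f"ins:{len(ins)}bp")
            )
    for ds, de in aln.deletions:
        matched = None
        for j in range(model.n_exons):
            s, e = offsets[j], offsets[j] + lengths[j]
            if de - ds == e - s and spliced[:ds] + spliced[de:] == spliced[:s] + spliced[e:]:
                matched = j
                break
            if abs(ds - s) <= EVENT_BOUNDARY_SLACK and abs(de - e) <= EVENT_BOUNDARY_SLACK:
                matched = j
                break
        if matched is not None:
            events.append(SpliceEvent(EventType.EXON_SKIP, matched))
        else:
            events.append(SpliceEvent(EventType.SNP, ds, f"del:{de - ds}bp"))
    for pos, ref, alt in aln.mismatches:
        events.append(SpliceEvent(EventType.SNP, pos, f"{ref}>{alt}"))
    return events


def _approx_equal(a: str, b: str, max_edits: int = 4) -> bool:
    """Cheap bounded comparison for intron-vs-insertion identity (tiny seqs)."""
    if a == b:
        return True
    if abs(len(a) - len(b)) > max_edits:
        return False
    # boundary ambiguity at repeat edges shows up as a rotation by <=2 bp
    for shift in range(1, EVENT_BOUNDARY_SLACK + 1):
        if a[shift:] == b[: len(a) - shift] or b[shift:] == a[: len(b) - shift]:
            return True
    mism = sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))
    return mism <= max_edits


def translate_cds(transcript: str, model: GeneModel, reference: str) -> Translation:
    """Locate the annotated CDS on the transcript by alignment and translate it.

    Translation uses the standard code from the mapped CDS start and stops at
    the first stop codon; a stop before the annotated CDS end is a truncation.
    """
    spliced = model.spliced_sequence(reference)
    aln = _align_to_spliced(transcript, spliced)
    if aln.identity < MIN_MODEL_IDENTITY:
        raise ValueError(f"CDS anchors unalignable for {model.gene_id}")
    q_start = aln.map_target_pos(model.cds_start)
    q_end = aln.map_target_pos(model.cds_end - 1) + 1
    cds = transcript[q_start:q_end]
    frameshift = len(cds) % 3 != 0
    n_codons = len(cds) // 3
    aa_full = str(Seq(cds[: 3 * n_codons]).translate())
    stop = aa_full.find("*")
    annotated_codons = (model.cds_end - model.cds_start) // 3 - 1  # minus stop
    if stop < 0:
        return Translation(aa_full, None, False, frameshift)
    return Translation(aa_full[:stop], stop, stop < annotated_codons, frameshift)


def classify_as_category(
    events_by_sex: Mapping[str, Sequence[SpliceEvent]],
    truncated_by_sex: Mapping[str, bool] | None = None,
) -> AsCategory:
    """Four-way category with precedence exon jump > intron jump > AA short.

    Requires transcripts from at least two sex types; substitution-only genes
    fall through to NO_CHANGE.
    """
    if len(events_by_sex) < 2:
        raise ValueError("need transcripts from >= 2 sex types to classify")
    kinds = {ev.kind for evs in events_by_sex.values() for ev in evs}
    if EventType.EXON_SKIP in kinds:
        return AsCategory.EXON_JUMP
    if EventType.INTRON_RETENTION in kinds:
        return AsCategory.INTRON_JUMP
    if truncated_by_sex and any(truncated_by_sex.values()):
        return AsCategory.AA_SHORT
    return AsCategory.NO_CHANGE


def classify_sex_group_type(
    presence: Mapping[str, bool], aa_identical: Mapping[frozenset, bool]
) -> SexGroupType:
    """Sex grouping from presence pattern plus pairwise AA identity.

    TYPE_1: exactly two sexes expressed, different AA.  TYPE_2: all three
    expressed, all mutually different.  TYPE_3: all three expressed, exactly
    one pair identical.  Anything else: NONE.
    """
    present = sorted(s for s in CORE_SEXES if presence.get(s))
    if len(present) == 2:
        pair = frozenset(present)
        return SexGroupType.TYPE_1 if not aa_identical[pair] else SexGroupType.NONE
    if len(present) == 3:
        pairs = [frozenset(p) for p in (("F", "M"), ("F", "H"), ("M", "H"))]
        same = sum(bool(aa_identical[p]) for p in pairs)
        if same == 0:
            return SexGroupType.TYPE_2
        if same == 1:
            return SexGroupType.TYPE_3
    return SexGroupType.NONE


@dataclass
class GeneClassification:
    gene_id: str
    category: AsCategory | None
    sex_group_type: SexGroupType
    events: dict[str, list[SpliceEvent]]
    translations: dict[str, Translation]


def classify_gene(
    transcripts_by_sex: Mapping[str, str], model: GeneModel, reference: str
) -> GeneClassification:
    """Full per-gene call: events, translations, category and sex-group type."""
    events: dict[str, list[SpliceEvent]] = {}
    translations: dict[str, Translation] = {}
    for sex in CORE_SEXES:
        seq = transcripts_by_sex.get(sex)
        if seq is None:
            continue
        events[sex] = align_to_model(seq, model, reference)
        translations[sex] = translate_cds(seq, model, reference)
    category = None
    if len(events) >= 2:
        category = classify_as_category(
            events, {s: t.truncated for s, t in translations.items()}
        )
    presence = {s: s in events for s in CORE_SEXES}
    aa = {s: t.aa for s, t in translations.items()}
    aa_identical = {
        frozenset((a, b)): aa[a] == aa[b]
        for i, a in enumerate(sorted(aa))
        for b in sorted(aa)[i + 1 :]
    }
    group = classify_sex_group_type(presence, aa_identical)
    return GeneClassification(model.gene_id, category, group, events, translations)


def classify_dataset(dataset: Dataset, whorl: str = "bud28") -> pd.DataFrame:
    """Classify every gene with >= 2 expressed sex types in a generated dataset."""
    rows = []
    for model in dataset.models:
        ts = dataset.transcript_sets[model.gene_id]
        by_sex = {}
        for sex in CORE_SEXES:
            rec = ts.transcript(sex, whorl)
            if rec is not None:
                by_sex[sex] = rec.sequence
        if len(by_sex) < 2:
            continue
        ref = dataset.references[model.reference_id]
        res = classify_gene(by_sex, model, ref)
        rows.append(
            {
                "gene_id": res.gene_id,
                "category": res.category.value if res.category else "",
                "sex_group_type": res.sex_group_type.value,
                "n_events": sum(len(v) for v in res.events.values()),
            }
        )
    return pd.DataFrame(rows)
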