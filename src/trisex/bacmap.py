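"""Assign sex-typed transcripts to reference regions and build presence tables.

Transcripts are aligned to the genomic references with a seed-and-extend
spliced aligner (exact 15-mer seeds chained colinearly, gaps filled by a
small edit-distance DP), so a transcript that retains an intron still maps
cleanly to its source gene.  Each transcript is assigned to at most one best
gene; per-gene presence across the three sex types feeds the candidate-gene
screens ("absent in females" and "expressed in two or three sex types").
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .synthio import CORE_SEXES, GeneModel, TranscriptRecord

logger = logging.getLogger(__name__)

SEED_K = 15
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_COVERAGE = 0.90
_MIN_INTRON = 20  # a reference gap at least this much longer than the
# transcript gap is treated as a spliced-out intron, not an indel


@dataclass(frozen=True)
class AlignmentHit:
    """Best spliced alignment of one transcript onto one gene."""

    transcript_id: str
    reference_id: str
    gene_id: str
    intervals: tuple[tuple[int, int], ...]  # chained, ordered, on the reference
    identity: float
    coverage: float

    @property
    def score(self) -> float:
        return self.identity * self.coverage


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance, O(len(a)*len(b)); used only on short gap fills."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        idx[seq[i : i + k]].append(i)
    return idx


def _chain_seeds(seeds: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Greedy colinear chain over (tx_pos, ref_pos) seeds sorted by tx_pos.

    Keeps seeds whose transcript and reference positions both advance; the
    reference may jump ahead of the transcript by up to ~20 kb (introns).
    """
    chain: list[tuple[int, int]] = []
    last_t, last_r = -1, -1
    for t, r in seeds:
        if not chain:
            chain.append((t, r))
            last_t, last_r = t, r
            continue
        dt, dr = t - last_t, r - last_r
        if dt <= 0 or dr <= 0:
            continue
        if dr - dt > 20_000 or dt - dr > 200:
            continue
        chain.append((t, r))
        last_t, last_r = t, r
    return chain


def _align_one(
    tx: str, ref: str, index: dict[str, list[int]], k: int = SEED_K
) -> tuple[tuple[tuple[int, int], ...], float, float] | None:
    """Chain exact seeds and fill gaps; returns (intervals, identity, coverage)."""
    seeds = []
    for t in range(0, len(tx) - k + 1):
        for r in index.get(tx[t : t + k], ()):
            seeds.append((t, r))
    if not seeds:
        return None
    # anchor on the most common diagonal to pick the right locus, then chain
    diag_counts: dict[int, int] = defaultdict(int)
    for t, r in seeds:
        diag_counts[r - t] += 1
    best_diag = max(diag_counts, key=lambda d: (diag_counts[d], -d))
    anchor_r = min(r for t, r in seeds if r - t == best_diag)
    window = [s for s in sorted(seeds) if -2000 < s[1] - anchor_r < 50_000]
    chain = _chain_seeds(window, k)
    if not chain:
        return None

    intervals: list[list[int]] = []
    aligned = 0
    edits = 0

    def add_interval(rs: int, re_: int) -> None:
        if intervals and rs <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], re_)
        else:
            intervals.append([rs, re_])

    # head extension: compare transcript prefix to the reference upstream
    t0, r0 = chain[0]
    head = min(t0, r0)
    if head:
        a, b = tx[t0 - head : t0], ref[r0 - head : r0]
        edits += sum(x != y for x, y in zip(a, b)) + (t0 - head)
        aligned += t0
        add_interval(r0 - head, r0)
    else:
        edits += t0
        aligned += t0

    prev_t, prev_r = t0, r0
    for t, r in chain[1:]:
        exact = max(0, min(k, t - prev_t))  # exact-match run from prev seed
        aligned += exact
        add_interval(prev_r, prev_r + exact)
        gt, gr = t - (prev_t + exact), r - (prev_r + exact)
        if gt > 0 or gr > 0:
            a = tx[prev_t + exact : t]
            b = ref[prev_r + exact : r]
            if gr - gt >= _MIN_INTRON:
                # spliced intron: align the transcript gap to the flanks only
                edits += edit_distance(a, b[: len(a)]) if a else 0
                aligned += gt
                if a:
                    add_interval(prev_r + exact, prev_r + exact + len(a))
            else:
                edits += edit_distance(a, b)
                aligned += max(gt, gr)
                add_interval(prev_r + exact, r)
        prev_t, prev_r = t, r
    aligned += k
    add_interval(prev_r, prev_r + k)

    # tail extension
    t_end, r_end = prev_t + k, prev_r + k
    tail = min(len(tx) - t_end, len(ref) - r_end)
    if tail:
        a, b = tx[t_end : t_end + tail], ref[r_end : r_end + tail]
        edits += sum(x != y for x, y in zip(a, b))
        aligned += tail
        add_interval(r_end, r_end + tail)
    edits += (len(tx) - t_end) - tail
    aligned += (len(tx) - t_end) - tail

    if aligned == 0:
        return None
    identity = max(0.0, 1.0 - edits / aligned)
    coverage = min(1.0, aligned / len(tx))
    return tuple(tuple(iv) for iv in intervals), identity, coverage


def _overlap(intervals: Sequence[tuple[int, int]], span: tuple[int, int]) -> int:
    s, e = span
    return sum(max(0, min(b, e) - max(a, s)) for a, b in intervals)


def map_transcripts(
    transcripts: Iterable[TranscriptRecord],
    references: dict[str, str],
    models: Sequence[GeneModel],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[AlignmentHit]:
    """Map each transcript to its best gene; hits below threshold are dropped.

    Ties on identity x coverage break toward the lowest reference id, then the
    lowest gene start coordinate; intergenic hits are discarded and logged.
    """
    if not references:
        raise ValueError("empty reference set")
    for thr in (min_identity, min_coverage):
        if not 0.0 < thr <= 1.0:
            raise ValueError("thresholds must be in (0, 1]")
    indexes = {rid: _kmer_index(seq, SEED_K) for rid, seq in sorted(references.items())}
    genes_by_ref: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        genes_by_ref[m.reference_id].append(m)

    hits: list[AlignmentHit] = []
    for tr in sorted(transcripts, key=lambda t: t.transcript_id):
        candidates: list[tuple[float, str, int, AlignmentHit]] = []
        for rid in sorted(references):
            res = _align_one(tr.sequence, references[rid], indexes[rid])
            if res is None:
                continue
            intervals, identity, coverage = res
            if identity < min_identity or coverage < min_coverage:
                continue
            best_gene, best_ov = None, 0
            for m in sorted(genes_by_ref[rid], key=lambda m: m.span[0]):
                ov = _overlap(intervals, m.span)
                if ov > best_ov:
                    best_gene, best_ov = m, ov
            if best_gene is None:
                logger.info("transcript %s: intergenic hit on %s discarded",
                            tr.transcript_id, rid)
                continue
            hit = AlignmentHit(tr.transcript_id, rid, best_gene.gene_id,
                               intervals, identity, coverage)
            candidates.append((hit.score, rid, best_gene.span[0], hit))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            logger.info("transcript %s: tie resolved toward %s",
                        tr.transcript_id, candidates[0][3].gene_id)
        hits.append(candidates[0][3])
    return hits


def build_presence_table(
    hits: Iterable[AlignmentHit], models: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-(reference, gene) presence of each core sex type (OR over transcripts).

    Covers every gene of every reference; ``n_sexes`` counts F/M/H presence.
    Transcript sex type is parsed from ``gene|sex|whorl`` transcript ids.
    """
    present: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        parts = h.transcript_id.split("|")
        sex = parts[1] if len(parts) > 1 else ""
        core = "H" if sex in ("HM", "HF") else sex
        if core in CORE_SEXES:
            present[h.gene_id].add(core)
    rows = []
    for m in sorted(models, key=lambda m: (m.reference_id, m.span[0])):
        sexes = present.get(m.gene_id, set())
        rows.append(
            {
                "reference_id": m.reference_id,
                "gene_id": m.gene_id,
                "gene_start": m.span[0],
                "F": "F" in sexes,
                "M": "M" in sexes,
                "H": "H" in sexes,
                "n_sexes": len(sexes),
            }
        )
    return pd.DataFrame(rows)


def presence_counts(table: pd.DataFrame) -> dict[int, int]:
    """Number of genes present in exactly k sex types, k = 1, 2, 3."""
    return {k: int((table["n_sexes"] == k).sum()) for k in (1, 2, 3)}


CANDIDATE_RULES = ("NOT_F_BUT_MH", "TWO_OR_THREE_SEXES")


def select_candidate_genes(table: pd.DataFrame, rule: str) -> list[str]:
    """Candidate-gene screen over the presence table.

    ``NOT_F_BUT_MH``: absent in females, expressed in both males and
    hermaphrodites.  ``TWO_OR_THREE_SEXES``: expressed in two or three sex
    types.  Results are sorted by (reference, gene coordinate).
    """
    if rule not in CANDIDATE_RULES:
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "NOT_F_BUT_MH":
        mask = ~table["F"] & table["M"] & table["H"]
    else:
        mask = table["n_sexes"].isin((2, 3))
    sel = table[mask].sort_values(["reference_id", "gene_start"])
    return list(sel["gene_id"])
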