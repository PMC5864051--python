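"""Seeded generator of synthetic inputs for trioecious sex-marker screening.

Emulates the structure of a papaya-style sex-determination study: three
chromosome classes (X, Yᵐ, Yʰ) carrying shared genes, sex-typed transcript
sets per floral whorl with planted SNPs and alternative-splicing events,
marker loci with engineered restriction-site SNPs, and cross progenies in
which dominant-allele (Y/Y class) combinations are zygotic-lethal.

Every planted difference is recorded in a truth ledger so downstream
classifiers can be scored exactly.  All randomness flows from one root seed
through named sub-streams, so a fixed config yields byte-identical output.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

SEX_TYPES = ("F", "M", "H", "HM", "HF")
CORE_SEXES = ("F", "M", "H")
WHORLS = ("bud28", "third", "fourth")

_BASES = np.array(list("ACGT"))
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)


class ChromClass(str, enum.Enum):
    """Sex-chromosome class of a reference region."""

    X = "X"
    Ym = "Ym"
    Yh = "Yh"


class MarkerClass(str, enum.Enum):
    """Which sexes a SNP marker distinguishes.

    THREE_SEX: three distinguishable alleles (one per chromosome class).
    FEMALE_TYPE: X-specific allele (Ym and Yh share the other allele).
    MALE_TYPE: Ym-specific allele (X and Yh share the other allele).
    """

    THREE_SEX = "THREE_SEX"
    FEMALE_TYPE = "FEMALE_TYPE"
    MALE_TYPE = "MALE_TYPE"


class EventType(str, enum.Enum):
    SNP = "SNP"
    INTRON_RETENTION = "INTRON_RETENTION"
    EXON_SKIP = "EXON_SKIP"
    PREMATURE_STOP = "PREMATURE_STOP"


_Y_CLASSES = frozenset({ChromClass.Ym, ChromClass.Yh})
_CHROM_ORDER = {ChromClass.X: 0, ChromClass.Ym: 1, ChromClass.Yh: 2}


@dataclass(frozen=True)
class SexGenotype:
    """A pair of sex-chromosome classes; Y/Y-class pairs are zygotic-lethal."""

    chrom_a: ChromClass
    chrom_b: ChromClass

    def __post_init__(self):
        a, b = sorted((self.chrom_a, self.chrom_b), key=_CHROM_ORDER.get)
        object.__setattr__(self, "chrom_a", a)
        object.__setattr__(self, "chrom_b", b)

    @property
    def label(self) -> str:
        return {ChromClass.X: "X", ChromClass.Ym: "Ym", ChromClass.Yh: "Yh"}[
            self.chrom_a
        ] + {ChromClass.X: "X", ChromClass.Ym: "Ym", ChromClass.Yh: "Yh"}[self.chrom_b]

    @property
    def is_lethal(self) -> bool:
        return self.chrom_a in _Y_CLASSES and self.chrom_b in _Y_CLASSES

    @property
    def phenotype(self) -> str | None:
        """Phenotypic sex: XX -> F, XYm -> M, XYh -> H; lethal pairs have none."""
        if self.is_lethal:
            return None
        return {"XX": "F", "XYm": "M", "XYh": "H"}[self.label]


XX = SexGenotype(ChromClass.X, ChromClass.X)
XYm = SexGenotype(ChromClass.X, ChromClass.Ym)
XYh = SexGenotype(ChromClass.X, ChromClass.Yh)

GENOTYPE_BY_LABEL = {"XX": XX, "XYm": XYm, "XYh": XYh}


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of a gene on a reference region.

    Coordinates are 0-based half-open on the reference; ``cds_start`` and
    ``cds_end`` are positions in spliced-transcript coordinates.
    """

    gene_id: str
    reference_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if e - s < 1:
                raise ValueError("exon length must be >= 1")
            if s <= prev_end - 1 and prev_end >= 0:
                raise ValueError("exons must be sorted and non-overlapping")
            if s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if not (0 <= self.cds_start < self.cds_end <= self.spliced_length):
            raise ValueError("CDS interval must lie within the spliced transcript")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_spliced_offsets(self) -> tuple[int, ...]:
        """Spliced-coordinate start of each exon."""
        offs, pos = [], 0
        for ln in self.exon_lengths:
            offs.append(pos)
            pos += ln
        return tuple(offs)

    def spliced_sequence(self, ref_seq: str) -> str:
        return "".join(ref_seq[s:e] for s, e in self.exons)

    def intron_sequences(self, ref_seq: str) -> tuple[str, ...]:
        return tuple(
            ref_seq[self.exons[i][1] : self.exons[i + 1][0]]
            for i in range(self.n_exons - 1)
        )

    def junction_positions(self) -> tuple[int, ...]:
        """Spliced-coordinate position of each exon/exon junction (end of exon i)."""
        offs = self.exon_spliced_offsets
        lens = self.exon_lengths
        return tuple(offs[i] + lens[i] for i in range(self.n_exons - 1))


@dataclass(frozen=True)
class PlantedEvent:
    """One ground-truth difference between a transcript and the base haplotype."""

    kind: EventType
    index: int  # spliced position (SNP/stop codon start) or intron/exon index
    ref: str = ""
    alt: str = ""

    def describe(self) -> str:
        if self.kind in (EventType.SNP, EventType.PREMATURE_STOP):
            return f"{self.ref}>{self.alt}"
        return ""


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    sex_type: str
    whorl: str
    sequence: str
    expression: float


@dataclass
class SexTranscriptSet:
    """Per-gene transcripts across sex types and whorls, plus planted truth."""

    gene_id: str
    records: dict[tuple[str, str], TranscriptRecord]
    events: dict[str, tuple[PlantedEvent, ...]]
    presence: dict[str, bool]

    def transcript(self, sex_type: str, whorl: str) -> TranscriptRecord | None:
        return self.records.get((sex_type, whorl))


@dataclass(frozen=True)
class MarkerDef:
    """A diagnostic SNP marker: alleles per chromosome class and melt Tm per allele."""

    name: str
    gene_id: str
    marker_class: MarkerClass
    spliced_pos: int
    alleles: Mapping[ChromClass, str]
    tm: Mapping[str, float]

    def allele_pair(self, genotype: SexGenotype) -> tuple[str, str]:
        pair = (self.alleles[genotype.chrom_a], self.alleles[genotype.chrom_b])
        return tuple(sorted(pair))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults are the generator's fixed study conditions: three reference
    regions (one per chromosome class), compact multi-exon genes, planted
    alternative-splicing events at 0.2 per gene per sex type and kind, and a
    96-sample hermaphrodite x male blind progeny.
    """

    seed: int = 0
    n_references: int = 3
    genes_per_reference: int = 6
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (90, 160)
    intron_len: tuple[int, int] = (60, 120)
    snp_sex_classes: tuple[MarkerClass, ...] = (
        MarkerClass.THREE_SEX,
        MarkerClass.FEMALE_TYPE,
        MarkerClass.MALE_TYPE,
    )
    as_event_rates: dict = field(
        default_factory=lambda: {
            EventType.INTRON_RETENTION: 0.2,
            EventType.EXON_SKIP: 0.2,
            EventType.PREMATURE_STOP: 0.2,
        }
    )
    nonsyn_snp_rate: float = 0.3
    presence_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)  # 3, 2, 1 sexes
    expression_lognormal_params: tuple[float, float] = (1.0, 0.5)
    elevated_multiplier: float = 8.0
    noise_sd_melt: float = 0.01
    delta_tm: float = 1.0
    progeny_n: int = 96

    def validate(self) -> None:
        for name in ("n_references", "genes_per_reference", "progeny_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} range is empty or invalid")
        rates = {EventType(k): float(v) for k, v in self.as_event_rates.items()}
        for v in list(rates.values()) + [self.nonsyn_snp_rate]:
            if not 0.0 <= v <= 1.0:
                raise ValueError("event rates must be probabilities in [0, 1]")
        if abs(sum(self.presence_probs) - 1.0) > 1e-9 or min(self.presence_probs) < 0:
            raise ValueError("presence_probs must be a probability vector")
        if self.snp_sex_classes and self.genes_per_reference < len(self.snp_sex_classes):
            raise ValueError(
                "genes_per_reference too small to host one marker gene per class"
            )
        # the smallest possible gene must still fit a >=60 nt CDS plus UTRs
        min_spliced = self.exons_per_gene[0] * self.exon_len[0]
        if min_spliced < 2 * _UTR_LEN_RANGE[0] + 60:
            raise ValueError("exon range too short for the requested CDS structure")


_UTR_LEN_RANGE = (24, 40)

# marker-class blueprints: engineered 3'UTR context (SNP offset within it) and
# the allele carried by each chromosome class.  CATATG / ACTAGT make the SNP a
# presence/absence NdeI or SpeI site for PCR-RFLP assays.
_MARKER_BLUEPRINTS = {
    MarkerClass.THREE_SEX: {
        "context": "CA_ATG",
        "alleles": {ChromClass.X: "C", ChromClass.Ym: "G", ChromClass.Yh: "T"},
    },
    MarkerClass.FEMALE_TYPE: {
        "context": "ACTAG_",
        "alleles": {ChromClass.X: "T", ChromClass.Ym: "A", ChromClass.Yh: "A"},
    },
    MarkerClass.MALE_TYPE: {
        "context": "GT_CAG",
        "alleles": {ChromClass.X: "A", ChromClass.Ym: "G", ChromClass.Yh: "A"},
    },
}

# named marker loci in the order THREE_SEX, FEMALE_TYPE, MALE_TYPE; exon counts
# give the female-type locus introns 5-7 and the male-type locus an intron 11.
_MARKER_LOCUS_NAMES = ("CpSVPL", "CpSERK", "CpCAF1AL")
_MARKER_LOCUS_EXONS = {"CpSVPL": 8, "CpSERK": 11, "CpCAF1AL": 12}


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _rand_sense_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), n)
    return "".join(_SENSE_CODONS[i] for i in idx)


def translate_to_first_stop(seq: str) -> str:
    """Translate from position 0 to (not including) the first stop codon."""
    n = len(seq) // 3
    aa = str(Seq(seq[: 3 * n]).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


@dataclass
class _GeneBuild:
    model: GeneModel
    spliced: str
    introns: tuple[str, ...]


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    reference_id: str,
    start: int,
    cfg: SimConfig,
    n_exons: int | None = None,
) -> tuple[_GeneBuild, str]:
    """Build one plus-strand gene; returns the build and its genomic sequence."""
    if n_exons is None:
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, n_exons)
    intron_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1, max(n_exons - 1, 0))
    spliced_len = int(exon_lens.sum())
    utr5 = int(rng.integers(*_UTR_LEN_RANGE))
    utr3 = int(rng.integers(*_UTR_LEN_RANGE))
    cds_len = spliced_len - utr5 - utr3
    cds_len -= cds_len % 3
    if cds_len < 60:
        raise ValueError(f"gene {gene_id}: exons too short for a 60 nt CDS")
    cds_start = utr5
    cds_end = utr5 + cds_len
    n_codons = cds_len // 3
    cds = "ATG" + _rand_sense_codons(rng, n_codons - 2) + _STOP_CODONS[int(rng.integers(0, 3))]
    spliced = _rand_dna(rng, utr5) + cds + _rand_dna(rng, spliced_len - utr5 - cds_len)

    exons, genomic_parts, pos, spl_off = [], [], start, 0
    for i, ln in enumerate(exon_lens):
        ln = int(ln)
        exons.append((pos, pos + ln))
        genomic_parts.append(spliced[spl_off : spl_off + ln])
        pos += ln
        spl_off += ln
        if i < n_exons - 1:
            il = int(intron_lens[i])
            intron = "GT" + _rand_dna(rng, il - 4) + "AG"
            genomic_parts.append(intron)
            pos += il
    genomic = "".join(genomic_parts)
    model = GeneModel(gene_id, reference_id, "+", tuple(exons), cds_start, cds_end)
    return _GeneBuild(model, spliced, model_introns(genomic_parts)), genomic


def model_introns(parts: Sequence[str]) -> tuple[str, ...]:
    return tuple(parts[1::2])


def apply_events(
    spliced: str,
    model: GeneModel,
    introns: Sequence[str],
    events: Iterable[PlantedEvent],
) -> tuple[str, int]:
    """Apply planted events to the base spliced sequence.

    Returns the variant transcript and the CDS start position within it
    (shifted by any insertion/deletion upstream of the annotated start).
    """
    edits: list[tuple[int, int, str]] = []  # (pos, deleted length, inserted seq)
    offsets = model.exon_spliced_offsets
    lens = model.exon_lengths
    junctions = model.junction_positions()
    for ev in events:
        if ev.kind in (EventType.SNP, EventType.PREMATURE_STOP):
            edits.append((ev.index, len(ev.ref), ev.alt))
        elif ev.kind == EventType.EXON_SKIP:
            edits.append((offsets[ev.index], lens[ev.index], ""))
        elif ev.kind == EventType.INTRON_RETENTION:
            edits.append((junctions[ev.index], 0, introns[ev.index]))
        else:  # pragma: no cover - exhaustive over EventType
            raise ValueError(ev.kind)
    seq = spliced
    cds_start = model.cds_start
    for pos, dlen, ins in sorted(edits, reverse=True):
        seq = seq[:pos] + ins + seq[pos + dlen :]
        if pos + dlen <= model.cds_start:
            cds_start += len(ins) - dlen
    return seq, cds_start


@dataclass
class Dataset:
    """Bundle of everything the pipeline consumes, plus the truth ledger."""

    config: SimConfig
    references: dict[str, str]
    reference_class: dict[str, ChromClass]
    models: list[GeneModel]
    transcript_sets: dict[str, SexTranscriptSet]
    markers: list[MarkerDef]
    progeny: pd.DataFrame
    ledger: pd.DataFrame
    truth: pd.DataFrame

    @property
    def transcripts(self) -> list[TranscriptRecord]:
        out = []
        for gene_id in sorted(self.transcript_sets):
            ts = self.transcript_sets[gene_id]
            for key in sorted(ts.records):
                out.append(ts.records[key])
        return out

    def model(self, gene_id: str) -> GeneModel:
        for m in self.models:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            outdir / "references.fasta",
            [(rid, self.references[rid], f"class={self.reference_class[rid].value}")
             for rid in sorted(self.references)],
        )
        write_fasta(
            outdir / "transcripts.fasta",
            [(t.transcript_id, t.sequence, f"expression={t.expression:.6g}")
             for t in self.transcripts],
        )
        write_gff(outdir / "models.gff3", self.models)
        self.ledger.to_csv(outdir / "truth_ledger.csv", index=False)
        self.truth.to_csv(outdir / "gene_truth.csv", index=False)
        self.progeny.to_csv(outdir / "progeny.csv", index=False)
        rows = []
        for mk in self.markers:
            rows.append(
                {
                    "name": mk.name,
                    "gene_id": mk.gene_id,
                    "marker_class": mk.marker_class.value,
                    "spliced_pos": mk.spliced_pos,
                    "alleles": json.dumps({c.value: a for c, a in mk.alleles.items()}),
                    "tm": json.dumps(mk.tm),
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "markers.csv", index=False)


def _sub_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _choose_presence(rng: np.random.Generator, probs) -> frozenset[str]:
    k = rng.choice((3, 2, 1), p=probs)
    if k == 3:
        return frozenset(CORE_SEXES)
    sexes = list(CORE_SEXES)
    idx = rng.permutation(3)[:k]
    return frozenset(sexes[i] for i in idx)


def _plant_marker(
    build: _GeneBuild, marker_class: MarkerClass, name: str, rng: np.random.Generator,
    delta_tm: float,
) -> tuple[_GeneBuild, MarkerDef]:
    """Engineer the marker context into the gene's 3'UTR (X allele is the base)."""
    bp = _MARKER_BLUEPRINTS[marker_class]
    context, alleles = bp["context"], bp["alleles"]
    off = context.index("_")
    p0 = build.model.cds_end + 4
    if p0 + len(context) > build.model.spliced_length:
        raise ValueError("3'UTR too short for marker context")
    ctx = context.replace("_", alleles[ChromClass.X])
    spliced = build.spliced[:p0] + ctx + build.spliced[p0 + len(ctx):]
    base_tm = 76.0 + float(rng.uniform(0.0, 4.0))
    distinct = sorted(set(alleles.values()))
    tm = {a: round(base_tm + i * delta_tm, 3) for i, a in enumerate(distinct)}
    marker = MarkerDef(name, build.model.gene_id, marker_class, p0 + off, dict(alleles), tm)
    return replace(build, spliced=spliced), marker


def _marker_snp_events(marker: MarkerDef) -> dict[str, PlantedEvent]:
    """Per-sex SNP events at the marker position (transcripts carry the expressed allele)."""
    base = marker.alleles[ChromClass.X]
    out = {}
    for sex, chrom in (("M", ChromClass.Ym), ("H", ChromClass.Yh)):
        alt = marker.alleles[chrom]
        if alt != base:
            out[sex] = PlantedEvent(EventType.SNP, marker.spliced_pos, base, alt)
    return out


def _plant_as_events(
    rng: np.random.Generator, build: _GeneBuild, cfg: SimConfig
) -> list[PlantedEvent]:
    """Plant at most one event per kind for one sex type; events never collide."""
    model = build.model
    rates = {EventType(k): float(v) for k, v in cfg.as_event_rates.items()}
    events: list[PlantedEvent] = []
    retained = None
    if model.n_exons > 1 and rng.random() < rates.get(EventType.INTRON_RETENTION, 0.0):
        retained = int(rng.integers(0, model.n_exons - 1))
        events.append(PlantedEvent(EventType.INTRON_RETENTION, retained))
    if rng.random() < rates.get(EventType.EXON_SKIP, 0.0):
        offs, lens = model.exon_spliced_offsets, model.exon_lengths
        candidates = [
            j
            for j in range(model.n_exons)
            if offs[j] > model.cds_start and offs[j] + lens[j] < model.cds_end - 3
            and (retained is None or j not in (retained, retained + 1))
        ]
        if candidates:
            events.append(
                PlantedEvent(EventType.EXON_SKIP, candidates[int(rng.integers(0, len(candidates)))])
            )
    skipped = next(
        (ev.index for ev in events if ev.kind == EventType.EXON_SKIP), None
    )
    clean = _clean_codon_positions(model, retained, skipped)
    if clean and rng.random() < rates.get(EventType.PREMATURE_STOP, 0.0):
        pos = clean[int(rng.integers(0, len(clean)))]
        ref = build.spliced[pos : pos + 3]
        if ref != "TAA":
            events.append(PlantedEvent(EventType.PREMATURE_STOP, pos, ref, "TAA"))
        clean = [p for p in clean if p != pos]
    if clean and rng.random() < cfg.nonsyn_snp_rate:
        pos = clean[int(rng.integers(0, len(clean)))]
        ref = build.spliced[pos : pos + 3]
        ref_aa = str(Seq(ref).translate())
        choices = [cod for cod in _SENSE_CODONS if str(Seq(cod).translate()) != ref_aa]
        alt = choices[int(rng.integers(0, len(choices)))]
        if ref not in _STOP_CODONS:
            events.append(PlantedEvent(EventType.SNP, pos, ref, alt))
    return events


def _clean_codon_positions(
    model: GeneModel, retained: int | None, skipped: int | None, margin: int = 8
) -> list[int]:
    """Spliced start positions of internal CDS codons clear of splice junctions
    and of any skipped exon, so point edits never blur a structural event."""
    n_codons = (model.cds_end - model.cds_start) // 3
    junctions = model.junction_positions()
    offsets, lengths = model.exon_spliced_offsets, model.exon_lengths
    out = []
    for c in range(2, n_codons - 2):
        pos = model.cds_start + 3 * c
        if any(j - margin <= pos <= j + margin or j - margin <= pos + 3 <= j + margin
               for j in junctions):
            continue
        if skipped is not None:
            s, e = offsets[skipped], offsets[skipped] + lengths[skipped]
            if s - margin <= pos <= e + margin:
                continue
        out.append(pos)
    return out


def _truth_category(kinds: set[EventType]) -> str:
    if EventType.EXON_SKIP in kinds:
        return "EXON_JUMP"
    if EventType.INTRON_RETENTION in kinds:
        return "INTRON_JUMP"
    if EventType.PREMATURE_STOP in kinds:
        return "AA_SHORT"
    return "NO_CHANGE"


def sex_group_type_from_aa(present: set[str], aa: Mapping[str, str]) -> str:
    """Spec rule shared by ledger truth and classifier: TYPE_1/2/3 or NONE."""
    present = sorted(set(present) & set(CORE_SEXES))
    if len(present) == 2:
        a, b = present
        return "TYPE_1" if aa[a] != aa[b] else "NONE"
    if len(present) == 3:
        pairs = [("F", "M"), ("F", "H"), ("M", "H")]
        same = [p for p in pairs if aa[p[0]] == aa[p[1]]]
        if not same:
            return "TYPE_2"
        if len(same) == 1:
            return "TYPE_3"
    return "NONE"


def generate_dataset(config: SimConfig) -> Dataset:
    """Generate the full input bundle: references, models, transcripts, markers,
    a blind H x M progeny, and the truth ledger."""
    config.validate()
    rngs = _sub_rngs(
        config.seed, ("genome", "presence", "events", "expression", "progeny", "melt")
    )
    g = rngs["genome"]

    classes = [list(ChromClass)[i % 3] for i in range(config.n_references)]
    yh_ref_index = next(
        (i for i, c in enumerate(classes) if c == ChromClass.Yh), config.n_references - 1
    )

    references: dict[str, str] = {}
    reference_class: dict[str, ChromClass] = {}
    models: list[GeneModel] = []
    builds: dict[str, _GeneBuild] = {}
    markers: list[MarkerDef] = []
    marker_events_by_gene: dict[str, dict[str, PlantedEvent]] = {}

    marker_names = dict(zip(config.snp_sex_classes, _MARKER_LOCUS_NAMES))

    for r, cls in enumerate(classes):
        ref_id = f"ref{r + 1}_{cls.value}"
        parts = [_rand_dna(g, int(g.integers(150, 300)))]
        pos = len(parts[0])
        for k in range(config.genes_per_reference):
            marker_class = None
            if r == yh_ref_index and k < len(config.snp_sex_classes):
                marker_class = config.snp_sex_classes[k]
            if marker_class is not None:
                gene_id = marker_names[marker_class]
                n_exons = _MARKER_LOCUS_EXONS.get(gene_id)
            else:
                gene_id = f"{ref_id}_g{k + 1:02d}"
                n_exons = None
            build, genomic = _build_gene(g, gene_id, ref_id, pos, config, n_exons)
            if marker_class is not None:
                build, marker = _plant_marker(
                    build, marker_class, f"{gene_id}_HRM", rngs["melt"], config.delta_tm
                )
                markers.append(marker)
                marker_events_by_gene[gene_id] = _marker_snp_events(marker)
                # re-splice the genomic copy so reference and spliced agree
                genomic = _resplice(build, genomic)
            parts.append(genomic)
            pos += len(genomic)
            spacer = _rand_dna(g, int(g.integers(150, 300)))
            parts.append(spacer)
            pos += len(spacer)
            models.append(build.model)
            builds[build.model.gene_id] = build
        references[ref_id] = "".join(parts)
        reference_class[ref_id] = cls

    # presence, events, expression
    pres_rng, ev_rng, expr_rng = rngs["presence"], rngs["events"], rngs["expression"]
    mu, sd = config.expression_lognormal_params
    transcript_sets: dict[str, SexTranscriptSet] = {}
    ledger_rows, truth_rows = [], []

    for model in models:
        build = builds[model.gene_id]
        is_marker_gene = model.gene_id in marker_events_by_gene
        if is_marker_gene:
            present = frozenset(CORE_SEXES)
        else:
            present = _choose_presence(pres_rng, config.presence_probs)

        events: dict[str, tuple[PlantedEvent, ...]] = {}
        for sex in CORE_SEXES:
            if sex not in present:
                events[sex] = ()
                continue
            evs = list(_plant_as_events(ev_rng, build, config))
            mk_ev = marker_events_by_gene.get(model.gene_id, {}).get(sex)
            if mk_ev is not None:
                evs.append(mk_ev)
            events[sex] = tuple(evs)

        aa: dict[str, str] = {}
        variant: dict[str, tuple[str, int]] = {}
        for sex in CORE_SEXES:
            if sex not in present:
                continue
            seq, cds_start = apply_events(build.spliced, model, build.introns, events[sex])
            variant[sex] = (seq, cds_start)
            aa[sex] = translate_to_first_stop(seq[cds_start:])

        records: dict[tuple[str, str], TranscriptRecord] = {}
        presence_all: dict[str, bool] = {}
        for sex in SEX_TYPES:
            core = "H" if sex in ("HM", "HF") else sex
            present_here = core in present
            presence_all[sex] = present_here
            if not present_here:
                continue
            seq = variant[core][0]
            for whorl in WHORLS:
                expr = float(expr_rng.lognormal(mu, sd))
                records[(sex, whorl)] = TranscriptRecord(
                    f"{model.gene_id}|{sex}|{whorl}", model.gene_id, sex, whorl, seq, expr
                )

        transcript_sets[model.gene_id] = SexTranscriptSet(
            model.gene_id, records, events, presence_all
        )

        for sex in CORE_SEXES:
            affected = {"F": "F", "M": "M", "H": "H;HM;HF"}[sex]
            for ev in events[sex]:
                ledger_rows.append(
                    {
                        "gene_id": model.gene_id,
                        "event_type": ev.kind.value,
                        "position": ev.index,
                        "detail": ev.describe(),
                        "sex_types": affected,
                    }
                )

        kinds = {ev.kind for sex in present for ev in events[sex]}
        kinds.discard(EventType.SNP)
        truth_rows.append(
            {
                "gene_id": model.gene_id,
                "reference_id": model.reference_id,
                "present_F": presence_all["F"],
                "present_M": presence_all["M"],
                "present_H": presence_all["H"],
                "n_sexes": sum(presence_all[s] for s in CORE_SEXES),
                "category": _truth_category(kinds) if len(present) >= 2 else "",
                "sex_group_type": sex_group_type_from_aa(set(present), aa)
                if len(present) >= 2
                else "NONE",
            }
        )

    progeny = generate_progeny((XYh, XYm), config.progeny_n, rng=rngs["progeny"], markers=markers)

    ledger = pd.DataFrame(
        ledger_rows, columns=["gene_id", "event_type", "position", "detail", "sex_types"]
    )
    truth = pd.DataFrame(truth_rows)
    return Dataset(
        config, references, reference_class, models, transcript_sets, markers,
        progeny, ledger, truth,
    )


def _resplice(build: _GeneBuild, genomic: str) -> str:
    """Rewrite exon sequence inside a genomic gene copy after editing the spliced seq."""
    model = build.model
    start = model.span[0]
    out = list(genomic)
    spl = 0
    for (s, e) in model.exons:
        ln = e - s
        out[s - start : e - start] = build.spliced[spl : spl + ln]
        spl += ln
    return "".join(out)


def generate_progeny(
    cross: tuple[SexGenotype, SexGenotype],
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    markers: Sequence[MarkerDef] = (),
) -> pd.DataFrame:
    """Simulate an F1 progeny; Y/Y-class zygotes are lethal and redrawn.

    For an XYh x XYm cross the surviving phenotype ratio F:H:M is 1:1:1.
    """
    p1, p2 = cross
    for p in (p1, p2):
        if p.label not in GENOTYPE_BY_LABEL:
            raise ValueError(f"parent genotype {p.label} not allowed")
    if p1.label == "XX" and p2.label == "XX":
        raise ValueError("XX x XX cross cannot produce progeny in this model")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    chroms1 = np.array([p1.chrom_a, p1.chrom_b], dtype=object)
    chroms2 = np.array([p2.chrom_a, p2.chrom_b], dtype=object)
    g1 = chroms1[rng.integers(0, 2, n)]
    g2 = chroms2[rng.integers(0, 2, n)]
    is_y = np.frompyfunc(lambda c: c in _Y_CLASSES, 1, 1)
    lethal = np.logical_and(is_y(g1).astype(bool), is_y(g2).astype(bool))
    # rejection sampling: redraw lethal zygotes until all survive
    while lethal.any():
        idx = np.nonzero(lethal)[0]
        g1[idx] = chroms1[rng.integers(0, 2, idx.size)]
        g2[idx] = chroms2[rng.integers(0, 2, idx.size)]
        lethal[idx] = np.logical_and(
            is_y(g1[idx]).astype(bool), is_y(g2[idx]).astype(bool)
        )

    genotypes = [SexGenotype(a, b) for a, b in zip(g1, g2)]
    rows = {
        "sample_id": [f"S{i + 1:05d}" for i in range(n)],
        "genotype": [g.label for g in genotypes],
        "phenotype": [g.phenotype for g in genotypes],
    }
    for mk in markers:
        rows[f"marker_{mk.name}"] = ["/".join(mk.allele_pair(g)) for g in genotypes]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flower cohort: per-sample locus measurements for functional mapping
# ---------------------------------------------------------------------------

# per-locus (expression class, AS flag) of each flower class, third whorl
# except females which are profiled in the fourth whorl.  AS at the female-type
# locus sits in introns 5-7, at the male-type locus in intron 11.
FLOWER_CLASS_PROFILES: dict[str, dict] = {
    "M": {"whorl": "third", "genotype": "XYm",
          "CpSERK": ("NOVAR", "NO_AS"), "CpSVPL": ("HIGH", "NO_AS"),
          "CpCAF1AL": ("HIGH", "NO_AS")},
    "H": {"whorl": "third", "genotype": "XYh",
          "CpSERK": ("NOVAR", "NO_AS"), "CpSVPL": ("LOW", "NO_AS"),
          "CpCAF1AL": ("HIGH", "NO_AS")},
    "HM": {"whorl": "third", "genotype": "XYh",
           "CpSERK": ("NOVAR", "AS"), "CpSVPL": ("HIGH", "NO_AS"),
           "CpCAF1AL": ("LOW", "AS")},
    "HF": {"whorl": "third", "genotype": "XYh",
           "CpSERK": ("NOVAR", "AS"), "CpSVPL": ("LOW", "NO_AS"),
           "CpCAF1AL": ("LOW", "AS")},
    "F": {"whorl": "fourth", "genotype": "XX",
          "CpSERK": ("NOVAR", "AS"), "CpSVPL": ("LOW", "NO_AS"),
          "CpCAF1AL": ("LOW", "AS")},
}

EXPRESSION_MULTIPLIER = {"HIGH": 8.0, "NOVAR": 1.0, "LOW": 0.125}

AS_RETAINED_INTRONS = {"CpSERK": (4, 5, 6), "CpCAF1AL": (10,)}


@dataclass
class LocusKit:
    """One named locus: model, sequences and its normal / AS transcript forms."""

    model: GeneModel
    reference: str
    spliced: str
    introns: tuple[str, ...]
    transcript_normal: str
    transcript_as: str
    retained_introns: tuple[int, ...]


@dataclass
class FlowerCohort:
    loci: dict[str, LocusKit]
    samples: pd.DataFrame  # sample_id, true_class, whorl, genotype
    expression: pd.DataFrame  # sample_id, locus, whorl, value
    transcripts: dict[tuple[str, str], str]  # (sample_id, locus) -> cDNA


def build_named_loci(seed: int = 7) -> dict[str, LocusKit]:
    """Construct the three canonical marker loci used in functional mapping."""
    cfg = SimConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    loci: dict[str, LocusKit] = {}
    pos = 0
    for name in _MARKER_LOCUS_NAMES:
        build, genomic = _build_gene(
            rng, name, f"{name}_region", 0, cfg, _MARKER_LOCUS_EXONS[name]
        )
        retained = AS_RETAINED_INTRONS.get(name, ())
        events = tuple(PlantedEvent(EventType.INTRON_RETENTION, i) for i in retained)
        as_seq, _ = apply_events(build.spliced, build.model, build.introns, events)
        loci[name] = LocusKit(
            build.model, genomic, build.spliced, build.introns,
            build.spliced, as_seq, tuple(retained),
        )
        pos += len(genomic)
    return loci


def generate_flower_cohort(
    n_per_class: int = 40,
    seed: int = 0,
    expression_noise_sd: float = 0.0,
) -> FlowerCohort:
    """Cohort of the five flower classes with per-locus expression and cDNA.

    Each sample is measured in its dissected whorl and, like the study's
    28-days-before-flowering whole buds, in a baseline ``bud28`` tissue where
    every locus sits at 1x; the baseline anchors the panel median for
    HIGH/LOW calls.  ``expression_noise_sd`` is the SD of multiplicative
    log-normal noise on the natural-log scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    loci = build_named_loci()
    sample_rows, expr_rows = [], []
    transcripts: dict[tuple[str, str], str] = {}
    i = 0
    for cls in ("F", "M", "H", "HM", "HF"):
        profile = FLOWER_CLASS_PROFILES[cls]
        for _ in range(n_per_class):
            i += 1
            sid = f"P{i:04d}"
            sample_rows.append(
                {"sample_id": sid, "true_class": cls,
                 "whorl": profile["whorl"], "genotype": profile["genotype"]}
            )
            for locus, kit in loci.items():
                expr_class, as_flag = profile[locus]
                mult = EXPRESSION_MULTIPLIER[expr_class]
                noise = float(np.exp(rng.normal(0.0, expression_noise_sd))) \
                    if expression_noise_sd > 0 else 1.0
                noise_b = float(np.exp(rng.normal(0.0, expression_noise_sd))) \
                    if expression_noise_sd > 0 else 1.0
                expr_rows.append({"sample_id": sid, "locus": locus,
                                  "whorl": profile["whorl"], "value": mult * noise})
                expr_rows.append({"sample_id": sid, "locus": locus,
                                  "whorl": "bud28", "value": 1.0 * noise_b})
                transcripts[(sid, locus)] = (
                    kit.transcript_as if as_flag == "AS" else kit.transcript_normal
                )
    return FlowerCohort(
        loci, pd.DataFrame(sample_rows), pd.DataFrame(expr_rows), transcripts
    )


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, records: Iterable[tuple[str, str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq, desc in records:
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_transcripts(path: str | Path) -> list[TranscriptRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        gene_id, sex, whorl = (parts + ["", "", ""])[:3]
        expr = 0.0
        for tok in rec.description.split():
            if tok.startswith("expression="):
                expr = float(tok.split("=", 1)[1])
        out.append(TranscriptRecord(rec.id, gene_id, sex, whorl, str(rec.seq).upper(), expr))
    return out


def write_gff(path: str | Path, models: Sequence[GeneModel]) -> None:
    """GFF3-like output; internal 0-based half-open becomes 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(
                f"{m.reference_id}\ttrisex\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            offs = m.exon_spliced_offsets
            for i, (xs, xe) in enumerate(m.exons):
                fh.write(
                    f"{m.reference_id}\ttrisex\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.e{i + 1};Parent={m.gene_id}\n"
                )
                # CDS portion of this exon, if any (spliced coords -> genomic)
                spl_s, spl_e = offs[i], offs[i] + (xe - xs)
                cs = max(spl_s, m.cds_start)
                ce = min(spl_e, m.cds_end)
                if cs < ce:
                    gs = xs + (cs - spl_s)
                    ge = xs + (ce - spl_s)
                    fh.write(
                        f"{m.reference_id}\ttrisex\tCDS\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t"
                        f"ID={m.gene_id}.cds;Parent={m.gene_id}\n"
                    )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse the GFF3-like gene models written by :func:`write_gff`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            ref, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start, end = int(start) - 1, int(end)  # back to 0-based half-open
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = {"ref": ref, "strand": strand, "exons": [], "cds": []}
                order.append(gid)
            elif ftype in ("exon", "CDS"):
                gid = attr["Parent"]
                genes[gid]["exons" if ftype == "exon" else "cds"].append((start, end))
    models = []
    for gid in order:
        d = genes[gid]
        exons = tuple(sorted(d["exons"]))
        offsets, pos = [], 0
        for s, e in exons:
            offsets.append(pos)
            pos += e - s

        def to_spliced(g: int) -> int:
            for (s, e), off in zip(exons, offsets):
                if s <= g < e:
                    return off + (g - s)
            raise ValueError(f"position {g} not exonic in {gid}")
        cds = sorted(d["cds"])
        cds_start = to_spliced(cds[0][0])
        last_s, last_e = cds[-1]
        cds_end = to_spliced(last_e - 1) + 1
        models.append(GeneModel(gid, d["ref"], d["strand"], exons, cds_start, cds_end))
    return models
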