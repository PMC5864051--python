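"""Generator contracts: determinism, lethality filtering, ledger completeness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisex import synthio
from trisex.synthio import (
    XX,
    ChromClass,
    EventType,
    MarkerClass,
    SexGenotype,
    SimConfig,
    XYh,
    XYm,
    generate_dataset,
    generate_progeny,
)


class TestSexGenotype:
    def test_chromosome_order_is_normalised(self):
        assert SexGenotype(ChromClass.Yh, ChromClass.X).label == "XYh"

    @pytest.mark.parametrize(
        "pair, lethal, phenotype",
        [
            ((ChromClass.X, ChromClass.X), False, "F"),
            ((ChromClass.X, ChromClass.Ym), False, "M"),
            ((ChromClass.X, ChromClass.Yh), False, "H"),
            ((ChromClass.Ym, ChromClass.Ym), True, None),
            ((ChromClass.Ym, ChromClass.Yh), True, None),
            ((ChromClass.Yh, ChromClass.Yh), True, None),
        ],
    )
    def test_lethality_and_phenotype(self, pair, lethal, phenotype):
        g = SexGenotype(*pair)
        assert g.is_lethal is lethal
        assert g.phenotype == phenotype


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_references": 0},
            {"exon_len": (50, 40)},
            {"as_event_rates": {EventType.EXON_SKIP: 1.5}},
            {"genes_per_reference": 2},  # fewer genes than marker classes
            {"exon_len": (20, 25)},  # too short for a 60 nt CDS
            {"presence_probs": (0.5, 0.5, 0.5)},
        ],
    )
    def test_contradictory_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(seed=0, **kwargs).validate()


class TestGenerateDataset:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=11)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg).write(d1)
        generate_dataset(cfg).write(d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_zero_as_rates_leave_only_marker_snps(self):
        cfg = SimConfig(
            seed=4,
            as_event_rates={k: 0.0 for k in EventType if k != EventType.SNP},
            nonsyn_snp_rate=0.0,
        )
        ds = generate_dataset(cfg)
        assert set(ds.ledger["event_type"]) <= {"SNP"}
        marker_genes = {m.gene_id for m in ds.markers}
        assert set(ds.ledger["gene_id"]) <= marker_genes
        # non-marker genes: all expressed sex types share one spliced sequence
        for gene_id, ts in ds.transcript_sets.items():
            if gene_id in marker_genes:
                continue
            seqs = {r.sequence for r in ts.records.values()}
            assert len(seqs) == 1

    def test_transcript_count_matches_presence_truth(self, dataset):
        # each present core sex contributes 3 whorls; HM/HF mirror H
        expected = 0
        for row in dataset.truth.itertuples():
            n_sex_types = row.present_F + row.present_M + 3 * row.present_H
            expected += 3 * n_sex_types
        assert len(dataset.transcripts) == expected

    def test_marker_classes_have_diagnostic_allele_patterns(self, dataset):
        by_class = {m.marker_class: m for m in dataset.markers}
        three = by_class[MarkerClass.THREE_SEX].alleles
        assert len(set(three.values())) == 3
        fem = by_class[MarkerClass.FEMALE_TYPE].alleles
        assert fem[ChromClass.Ym] == fem[ChromClass.Yh] != fem[ChromClass.X]
        male = by_class[MarkerClass.MALE_TYPE].alleles
        assert male[ChromClass.X] == male[ChromClass.Yh] != male[ChromClass.Ym]

    def test_ledger_explains_every_sequence_difference(self, dataset):
        """Transcripts without planted events equal the annotated spliced
        sequence; SNP-only transcripts differ from it exactly inside the
        ledger's recorded edit spans."""
        structural = {EventType.INTRON_RETENTION, EventType.EXON_SKIP}
        checked = 0
        for model in dataset.models:
            ts = dataset.transcript_sets[model.gene_id]
            spliced = model.spliced_sequence(dataset.references[model.reference_id])
            for sex in synthio.CORE_SEXES:
                rec = ts.transcript(sex, "bud28")
                if rec is None:
                    continue
                events = ts.events[sex]
                if not events:
                    assert rec.sequence == spliced
                    checked += 1
                elif not any(e.kind in structural for e in events):
                    assert len(rec.sequence) == len(spliced)
                    spans = set()
                    for e in events:
                        spans.update(range(e.index, e.index + max(len(e.ref), 1)))
                    diffs = {
                        i for i, (a, b) in enumerate(zip(spliced, rec.sequence)) if a != b
                    }
                    assert diffs <= spans and diffs
                    checked += 1
        assert checked > 0


class TestGenerateProgeny:
    def test_three_sex_cross_segregates_one_one_one(self):
        prog = generate_progeny((XYh, XYm), 300_000, seed=42)
        freqs = prog["phenotype"].value_counts(normalize=True)
        for sex in ("F", "H", "M"):
            assert abs(freqs[sex] - 1 / 3) < 0.005

    def test_lethal_genotypes_never_emitted(self):
        prog = generate_progeny((XYh, XYm), 5000, seed=1)
        assert set(prog["genotype"]) <= {"XX", "XYm", "XYh"}

    def test_female_by_male_cross_yields_f_and_m_only(self):
        prog = generate_progeny((XX, XYm), 100, seed=2)
        assert set(prog["phenotype"]) == {"F", "M"}

    def test_female_by_female_cross_is_an_error(self):
        with pytest.raises(ValueError):
            generate_progeny((XX, XX), 10, seed=0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 60))
    def test_progeny_rows_always_viable_and_consistent(self, seed, n):
        prog = generate_progeny((XYh, XYm), n, seed=seed)
        assert len(prog) == n
        expected_pheno = {"XX": "F", "XYm": "M", "XYh": "H"}
        for row in prog.itertuples():
            assert row.phenotype == expected_pheno[row.genotype]

    def test_marker_allele_pairs_follow_genotype(self, dataset):
        marker = dataset.markers[0]  # three-sex marker: X=C, Ym=G, Yh=T
        prog = generate_progeny((XYh, XYm), 50, seed=3, markers=[marker])
        col = f"marker_{marker.name}"
        want = {"XX": "C/C", "XYm": "C/G", "XYh": "C/T"}
        for row in prog.itertuples():
            assert getattr(row, col) == want[row.genotype]


class TestRoundTripIO:
    def test_fasta_and_gff_round_trip(self, dataset, tmp_path):
        dataset.write(tmp_path)
        refs = synthio.read_fasta(tmp_path / "references.fasta")
        assert refs == dataset.references
        models = synthio.read_gene_models(tmp_path / "models.gff3")
        by_id = {m.gene_id: m for m in models}
        for m in dataset.models:
            back = by_id[m.gene_id]
            assert back.exons == m.exons
            assert (back.cds_start, back.cds_end) == (m.cds_start, m.cds_end)
        txs = synthio.read_transcripts(tmp_path / "transcripts.fasta")
        assert len(txs) == len(dataset.transcripts)
        assert txs[0].sequence == dataset.transcripts[0].sequence

    def test_reference_cds_translates_without_internal_stop(self, dataset):
        for model in dataset.models:
            spliced = model.spliced_sequence(dataset.references[model.reference_id])
            cds = spliced[model.cds_start : model.cds_end]
            assert len(cds) % 3 == 0
            aa = synthio.translate_to_first_stop(cds)
            assert len(aa) == len(cds) // 3 - 1  # stop only at the end
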