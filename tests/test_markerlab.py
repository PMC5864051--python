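"""In-silico PCR, restriction digestion and HRM melt-curve analysis."""

import numpy as np
import pytest

from trisex import markerlab, synthio
from trisex.markerlab import (
    Amplicon,
    MeltCurve,
    PrimerPair,
    cluster_melt,
    default_grid,
    digest,
    in_silico_pcr,
    normalize_melt,
    revcomp,
    simulate_melt,
)

_BASES = np.array(list("ACGT"))


def _rand_dna(rng, n):
    return "".join(_BASES[rng.integers(0, 4, n)])


def _naive_pcr(template, fwd, rev, max_len=5000):
    """Quadratic scan oracle: every (forward, reverse-complement) pairing."""
    rc = revcomp(rev)
    f_sites = [i for i in range(len(template)) if template.startswith(fwd, i)]
    r_sites = [i for i in range(len(template)) if template.startswith(rc, i)]
    out = []
    for f in f_sites:
        for r in r_sites:
            end = r + len(rev)
            if r >= f + len(fwd) and end - f <= max_len:
                out.append((f, end))
    return sorted(out, key=lambda p: (p[1] - p[0], p[0]))


class TestInSilicoPcr:
    def test_hand_computed_amplicon(self):
        rng = np.random.default_rng(1)
        fwd, rev = _rand_dna(rng, 18), _rand_dna(rng, 18)
        template = "AAAA" + fwd + "C" * 10 + revcomp(rev) + "TTTT"
        products = in_silico_pcr(template, PrimerPair("p", fwd, rev))
        assert len(products) == 1
        amp = products[0]
        assert amp.length == 18 + 10 + 18 == 46
        assert amp.sequence == template[4:50]

    def test_absent_primers_give_no_product(self):
        products = in_silico_pcr("ACGT" * 50, PrimerPair("p", "T" * 16, "G" * 16))
        assert products == []

    def test_junction_primer_fails_on_intron_retention(self, named_loci):
        kit = named_loci["CpSERK"]
        primers = markerlab.design_junction_primers(kit.model, kit.reference)
        for i in kit.retained_introns:
            pair, expected = primers[i]
            normal = in_silico_pcr(kit.transcript_normal, pair)
            assert normal and normal[0].length == expected
            assert in_silico_pcr(kit.transcript_as, pair) == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            PrimerPair("p", "ACGTACGTACGT", "ACGTACGTACGTACGT")

    def test_fuzz_agrees_with_naive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            template = _rand_dna(rng, int(rng.integers(60, 400)))
            if rng.random() < 0.7:  # plant primers so products actually occur
                f0 = int(rng.integers(0, len(template) - 40))
                fwd = template[f0 : f0 + 16]
                r0 = int(rng.integers(f0 + 16, len(template) - 16))
                rev = revcomp(template[r0 : r0 + 16])
            else:
                fwd, rev = _rand_dna(rng, 16), _rand_dna(rng, 16)
            got = in_silico_pcr(template, PrimerPair("p", fwd, rev), max_products=10**6)
            assert [(a.start, a.end) for a in got] == _naive_pcr(template, fwd, rev)


class TestDigest:
    def test_single_ndei_site_cut_offsets(self):
        rng = np.random.default_rng(3)
        seq = _rand_dna(rng, 97).replace("CATATG", "CATTTG") + "CATATG" + _rand_dna(
            rng, 97
        ).replace("CATATG", "CATTTG")
        amp = Amplicon("t", 0, 200, seq)
        res = digest(amp, "NdeI")
        assert res.fragments == (99, 101)

    def test_no_site_single_fragment(self):
        seq = "A" * 200
        res = digest(Amplicon("t", 0, 200, seq), "SpeI")
        assert res.fragments == (200,)

    def test_two_sites_three_fragments(self):
        seq = "G" * 40 + "ACTAGT" + "C" * 30 + "ACTAGT" + "G" * 18
        res = digest(Amplicon("t", 0, len(seq), seq), "SpeI")
        assert len(res.fragments) == 3
        assert sum(res.fragments) == len(seq)
        assert res.fragments[0] == 41  # A^CTAGT cuts after one base of the site

    def test_unknown_enzyme(self):
        with pytest.raises(ValueError):
            digest(Amplicon("t", 0, 4, "ACGT"), "EcoRI")

    def test_fuzz_matches_biopython_and_sums(self):
        from Bio.Restriction import NdeI, SpeI
        from Bio.Seq import Seq

        enzymes = {"NdeI": NdeI, "SpeI": SpeI}
        rng = np.random.default_rng(11)
        for _ in range(2000):
            name = ("NdeI", "SpeI")[int(rng.integers(0, 2))]
            seq = _rand_dna(rng, int(rng.integers(20, 300)))
            if rng.random() < 0.6:  # plant 1-3 sites
                site = markerlab.ENZYMES[name][0]
                for _k in range(int(rng.integers(1, 4))):
                    p = int(rng.integers(0, len(seq) - 6))
                    seq = seq[:p] + site + seq[p + 6 :]
            res = digest(Amplicon("t", 0, len(seq), seq), name)
            assert sum(res.fragments) == len(seq)
            cuts = enzymes[name].search(Seq(seq))  # 1-based first base after cut
            bounds = [0] + [c - 1 for c in sorted(cuts)] + [len(seq)]
            want = tuple(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
            got = tuple(f for f in res.fragments if f > 0)
            assert got == want


class TestSimulateMelt:
    TM = {"A": 78.0, "B": 80.0}

    def test_homozygote_midpoint_is_half(self):
        curve = simulate_melt(("A", "A"), self.TM)
        at_tm = curve.fluorescence[np.isclose(curve.temperature, 78.0)]
        assert at_tm == pytest.approx(0.5)

    def test_heterozygote_is_mean_of_four_logistics(self):
        curve = simulate_melt(("A", "B"), self.TM, slope=0.5, het_delta_tm=1.0)
        t = curve.temperature

        def logi(tm):
            return 1.0 / (1.0 + np.exp((t - tm) / 0.5))

        want = (logi(78.0) + logi(80.0) + logi(77.0) + logi(79.0)) / 4.0
        np.testing.assert_allclose(curve.fluorescence, want, atol=1e-12)

    def test_same_seed_reproduces_noise(self):
        c1 = simulate_melt(("A", "A"), self.TM, noise_sd=0.02, seed=9)
        c2 = simulate_melt(("A", "A"), self.TM, noise_sd=0.02, seed=9)
        np.testing.assert_array_equal(c1.fluorescence, c2.fluorescence)

    def test_tm_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_melt(("A", "A"), {"A": 95.0})

    def test_non_ascending_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_melt(("A", "A"), self.TM, grid=np.array([70.0, 69.0, 71.0]))


class TestNormalizeMelt:
    def test_ideal_curve_is_unchanged(self):
        curve = simulate_melt(("A", "A"), {"A": 77.0})
        norm = normalize_melt(curve)
        interior = (curve.temperature > 68) & (curve.temperature < 87)
        np.testing.assert_allclose(
            norm.fluorescence[interior], curve.fluorescence[interior], atol=1e-6
        )

    def test_affine_transform_is_removed(self):
        base = simulate_melt(("A", "B"), {"A": 77.0, "B": 79.0})
        scaled = MeltCurve(base.temperature, 3.0 * base.fluorescence + 2.0)
        norm = normalize_melt(scaled)
        np.testing.assert_allclose(norm.fluorescence, normalize_melt(base).fluorescence,
                                   atol=1e-6)

    def test_flat_curve_is_degenerate(self):
        t = default_grid()
        with pytest.raises(ValueError):
            normalize_melt(MeltCurve(t, np.ones_like(t)))

    def test_tiny_window_rejected(self):
        curve = simulate_melt(("A", "A"), {"A": 77.0})
        with pytest.raises(ValueError):
            normalize_melt(curve, pre_window=(65.0, 65.3))


def _three_genotype_curves(noise_sd, seed, n_blind=30):
    tm = {"C": 77.0, "G": 78.0, "T": 79.0}
    rng = np.random.default_rng(seed)
    curves, reference, truth = [], {}, {}
    pairs = {"F": ("C", "C"), "M": ("C", "G"), "H": ("C", "T")}
    i = 0
    for label, pair in pairs.items():
        for k in range(3 + n_blind):
            i += 1
            sid = f"s{i:03d}"
            curves.append(
                normalize_melt(
                    simulate_melt(pair, tm, noise_sd=noise_sd, seed=rng,
                                  sample_id=sid, marker="mk")
                )
            )
            truth[sid] = label
            if k < 3:
                reference[sid] = label
    return curves, reference, truth


class TestClusterMelt:
    def test_noise_free_genotypes_separate_perfectly(self):
        curves, ref, truth = _three_genotype_curves(0.0, 1)
        res = cluster_melt(curves, ref)
        assert all(v == 100.0 for v in res.correlation_pct.values())
        assert all(c.cluster == truth[c.sample_id] for c in res.calls)

    def test_shared_allele_classes_co_cluster(self, dataset):
        """At a female-type marker the Ym and Yh alleles coincide, so male and
        hermaphrodite samples fall in one pooled cluster."""
        marker = next(
            m for m in dataset.markers
            if m.marker_class is synthio.MarkerClass.FEMALE_TYPE
        )
        assert markerlab.marker_cluster_label(marker, synthio.XYm) == "H+M"
        assert markerlab.marker_cluster_label(marker, synthio.XYh) == "H+M"
        assert markerlab.marker_cluster_label(marker, synthio.XX) == "F"

    def test_assignment_is_order_invariant(self):
        curves, ref, _ = _three_genotype_curves(0.01, 2)
        res_fwd = cluster_melt(curves, ref)
        res_rev = cluster_melt(curves[::-1], ref)
        assert {(c.sample_id, c.cluster) for c in res_fwd.calls} == {
            (c.sample_id, c.cluster) for c in res_rev.calls
        }

    def test_grid_subsampling_by_two_preserves_assignments(self):
        curves, ref, _ = _three_genotype_curves(0.01, 3)
        sub = [
            MeltCurve(c.temperature[::2], c.fluorescence[::2], c.sample_id, c.marker)
            for c in curves
        ]
        full = cluster_melt(curves, ref)
        half = cluster_melt(sub, ref)
        assert {(c.sample_id, c.cluster) for c in full.calls} == {
            (c.sample_id, c.cluster) for c in half.calls
        }

    def test_no_reference_samples_is_an_error(self):
        curves, _, _ = _three_genotype_curves(0.0, 4)
        with pytest.raises(ValueError):
            cluster_melt(curves, {})
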