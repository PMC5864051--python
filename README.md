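# trisex

Sex-linked marker screening and functional mapping for a trioecious plant.

Papaya-type species carry three sex forms — female (XX), male (XY<sup>m</sup>)
and hermaphrodite (XY<sup>h</sup>) — controlled by one locus with alleles
*m* ↔ X, *M₁* ↔ Y<sup>m</sup> and *M₂* ↔ Y<sup>h</sup>; every combination of
two dominant alleles (Y/Y-class genotypes) is lethal to the zygote.
Breeders need DNA markers that tell the three sexes apart at the seedling
stage and, ideally, flag *stable* hermaphrodites, because hermaphrodite
flowers drift into female-sterile (HM) and carpellate (HF) abnormal forms.

`trisex` implements the complete desk side of such a screen as a tested
Python library with a CLI:

* **`trisex.synthio`** — seeded generator of every input the pipeline
  consumes: reference regions per chromosome class, gene models, sex-typed
  transcripts per floral whorl with planted SNPs and splicing events, marker
  loci, and H × M cross progenies with Y/Y lethality (rejection sampling).
  Every planted difference is recorded in a truth ledger.
* **`trisex.bacmap`** — spliced seed-and-extend alignment of transcripts to
  the references, per-gene presence across sex types, and the two candidate
  screens (*absent in females*, *expressed in 2–3 sex types*).
* **`trisex.asclass`** — splice-event calls against the gene model (intron
  retention, exon skip), CDS translation with premature-stop detection, the
  four-way category (exon jump > intron jump > AA short > no change) and the
  presence/amino-acid sex grouping (type_1 / type_2 / type_3).
* **`trisex.markerlab`** — exact-match in-silico PCR, NdeI/SpeI restriction
  digestion (PCR–RFLP), junction RT-PCR for splicing flags, and
  high-resolution-melting (HRM) simulation, normalisation and
  difference-curve clustering.
* **`trisex.segtest`** — Pearson chi-squared goodness-of-fit of pooled
  progeny counts against the marker-class segregation ratio:

  ```
  χ² = Σᵢ (Oᵢ − Eᵢ)² / Eᵢ,   Eᵢ = N·rᵢ/Σr,   df = k − 1
  ```

  with 1:1:1 (three-sex marker), 1:2 (female-type, M+H pooled) and
  2:1 (male-type, F+H pooled) ratios; no continuity correction.
* **`trisex.wholemap`** — the functional map: per-locus
  (expression class, AS flag, genotype) triples at CpSERK / CpSVPL /
  CpCAF1AL are matched against a data-driven rule table to call the flower
  type (M, H, HM, HF, fourth-whorl F) and the stable-hermaphrodite flag.

## Worked example

```python
from trisex import synthio, bacmap, asclass, segtest, markerlab

ds = synthio.generate_dataset(synthio.SimConfig(seed=1))

hits = bacmap.map_transcripts(ds.transcripts, ds.references, ds.models)
table = bacmap.build_presence_table(hits, ds.models)
print(bacmap.presence_counts(table))
# {1: 1, 2: 6, 3: 11}   genes expressed in exactly 1, 2, 3 sex types

rep = asclass.classify_dataset(ds)
print(rep["category"].value_counts().to_dict())
# {'EXON_JUMP': 10, 'NO_CHANGE': 4, 'INTRON_JUMP': 3}

obs = segtest.pool_counts({"F": 42, "H": 30, "M": 24},
                          synthio.MarkerClass.FEMALE_TYPE)
res = segtest.chi_square_gof(obs)
print(f"chi2={res.chi2_rounded}, df={res.df}, significant={res.significant}")
# chi2=4.69, df=1, significant=True   (42 vs 54 pooled M+H against 1:2)

curves, ref, truth = markerlab.simulate_marker_hrm(ds.markers[0], ds.progeny,
                                                   noise_sd=0.01, seed=1)
result = markerlab.cluster_melt(curves, ref)
print(result.correlation_pct)   # {'F': 100.0, 'H': 100.0, 'M': 100.0}
print(result.blind_counts)      # {'M': 30, 'F': 29, 'H': 25} -> 1:1:1 segtest
```

The chi-squared call reads: 42 females versus 54 non-females in a 96-seedling
blind progeny deviates significantly from the expected 1:2, so that marker's
segregation is distorted; the HRM clustering recovered every known-sex
reference sample (100 % correlation) and assigned the blind samples to
near-1:1:1 genotype clusters.

The same steps are available from the shell:

```bash
trisex simulate --out data --seed 1
trisex map --references data/references.fasta --transcripts data/transcripts.fasta \
           --models data/models.gff3 --out presence.tsv
trisex screen --presence presence.tsv --rule TWO_OR_THREE_SEXES --out candidates.txt
trisex run-all --out results --seed 1
```

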