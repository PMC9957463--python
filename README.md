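# seedprotdev

Proteomics of developing seeds and nuts: a tested, reusable pipeline for the
analyses behind a nut-development proteomic survey of pecan (*Carya
illinoinensis*) — allergen marker-peptide selection with modification-aware
monoisotopic *m/z*, the multi-criterion 2-D gel differential spot filter,
presence–absence/GO trend analysis of shotgun identifications, and targeted
extracted-ion chromatograms (EICs) — plus a synthetic-data generator with
planted ground truth so every stage is testable without raw instrument data.

It is written for proteomics practitioners who want to apply (or audit) this
style of analysis: food-allergen assay developers screening tryptic marker
peptides, and lab groups running comparative 2-D gel or label-free
presence–absence studies of developing seeds.

## The methods

**Marker peptides.** Candidate allergen markers are fully tryptic peptides
(cleavage C-terminal to K/R, no cleavage before Pro by default) with no
missed cleavages and length 7–25 aa. Candidates are annotated and excluded
when they overlap a cleavable signal-peptide span (absent from the mature
protein) or occur as a substring of a homologous allergen (non-specific, e.g.
shared between pecan and walnut vicilins). Theoretical ions use monoisotopic
residue masses, water 18.010565 Da, proton 1.0072765 Da, fixed
carbamidomethyl-Cys (+57.021464 Da) and optional N-terminal Gln→pyroGlu
(−17.026549 Da):

    m/z = (M + z·1.0072765) / z

**2-D gel differentials.** Spot intensities are normalized to *spot
percentages* (per-gel sum = 100). With a 2 cultivars × 2 time points design
(2 replicate gels per cell), a spot is differentially accumulated when
(1) the pooled means change ≥ 2-fold with two-sided t-test p < 0.05 (n = 4
per side); (2) the ≥ 2-fold change holds within each subgroup individually
(n = 2); (3) the highest cell mean is ≥ ¼ of the mean spot percentage of all
spots (= 0.25 × 100/n_spots); and optionally (4) criteria 1–2 re-confirmed
with an alternate replacement sample group.

**Presence–absence and GO trends.** A protein is accepted in a sample when it
has ≥ 2 matching peptides or a search score > 40, with p < 0.05; replicates
within a (cultivar, stage) cell are union-merged. GO terms are ranked by
their highest per-cell count of present proteins; an early-vs-late trend test
flags terms whose per-(stage, cultivar) counts differ > 2-fold with p < 0.05
between the first and last three stages (this is how fading histone terms are
detected during kernel maturation).

**EICs.** Per scan, intensities of centroided peaks within ± tol ppm of the
target *m/z* (inclusive bounds, ppm relative to the target; default 20 ppm)
are summed; an ion is called present when ≥ 3 consecutive scans exceed an
intensity threshold.

## Worked example

Generate a synthetic study (300 spots, 12 planted 4-fold changes, 24
proteins) and run the full pipeline:

```sh
$ seedprotdev simulate --seed 42 --out demo --n-spots 300 --n-diff-spots 12 --n-proteins 24
$ seedprotdev pipeline --config demo/pipeline.yaml
marker_candidates                            7
marker_peptides                              4
differential_spots        {'up': 7, 'down': 5}
proteins_detected                           24
go_terms_ranked                              0
go_terms_flagged      [GO:SIM0001, GO:SIM0002]
ion_presence_calls                           4
```

The planted 2S-albumin-like allergen yields 7 tryptic candidates, of which 1
overlaps the signal span, 2 are shared with the homolog and 4 survive as
markers; 12 planted spot fold-changes are all recovered (7 up, 5 down for
this seed); the two planted "early-only" GO terms are flagged by the trend
test; and the 4 marker ions are detected only in the mature-stage peak list
(4 presence calls). Theoretical ions for two real pecan allergen marker
peptides:

```sh
$ seedprotdev mz --peptide NFLAGQNNIINQLER -z 2 --no-cam
872.4605
$ seedprotdev mz --peptide QQQQEEGIRGEEMEEMVQCASDLPK -z 3 --pyro
978.0968
```

Both sit within 20 ppm of the observed values (872.4482 and 978.0988)
reported for Car i 2 and Car i 1.

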