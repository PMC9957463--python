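# Methods

This note documents the models and procedures implemented in `seedprotdev`,
the parameters that matter, the synthetic-data generator's assumptions, and
the numerical choices made where conventions differ between tools.

## In-silico digestion and peptide ions

Trypsin cleavage is modelled C-terminal to K/R; the classical proline rule
(no cleavage at a K/R–P junction) is on by default and configurable, since
published peptide counts for the same protein differ between engines that do
and do not apply it. Peptides carry 1-based inclusive coordinates in their
parent so that overlap with an annotated signal-peptide span is a closed-
interval test (any shared residue counts as overlap). With `max_missed = k`,
the digest is exactly the set of contiguous merges of ≤ k adjacent
zero-missed fragments; the test suite checks this against brute-force
enumeration on random sequences.

Masses are monoisotopic throughout: residue masses to 6 decimals, water
18.010565 Da, proton 1.0072765 Da. Two modifications are supported, matching
an iodoacetamide-alkylated digest of seed storage proteins:
carbamidomethyl-Cys (+57.021464 Da, fixed) and N-terminal Gln→pyroglutamate
(−17.026549 Da, variable, valid only on a Gln N-terminus). Reported *m/z*
values are rounded to 4 decimals, the precision customary for Q-TOF work.
Observed instrument values are expected to deviate from theory; the five
reference allergen ions shipped in `reference_data.py` deviate by 2–18 ppm,
inside the ±20 ppm precursor tolerance used for matching.

## Marker-peptide selection

Candidates are zero-missed-cleavage tryptic peptides of length 7–25 aa (the
range recommended for food-allergen detection assays). Two exclusions apply:

- **Signal-span overlap** — the mature protein lacks the signal peptide, so
  a marker inside (or touching) the span would not be observable in food.
- **Non-specificity** — the candidate occurs as a *substring* of a homolog
  sequence. Substring matching is deliberately stricter than comparing
  digests: a shared tract is non-specific regardless of the homolog's
  cleavage context. Optional I/L-equivalence collapses the isobaric
  leucine/isoleucine before matching (off by default).

The output is a per-candidate ledger with a pass/fail column per rule rather
than a filtered list, so each exclusion is auditable and the criteria can be
re-scored under different settings without re-digesting.

## Isoelectric points

Net charge at a given pH is the Henderson–Hasselbalch sum over the free
termini and the D/E/C/Y (acidic) and H/K/R (basic) side chains. The charge
is strictly decreasing in pH, so the pI is the unique root, found by
bisection on [0, 14] to |ΔpH| ≤ 0.001. Two named pKa tables are provided and
printed in `isoelectric.PKA_TABLES`: `bjellqvist` (default; nterm 7.5,
cterm 3.55, K 10.0, R 12.0, H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0) and
`emboss` (nterm 8.6, cterm 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
Y 10.1). For a free glycine the two give 5.52 and 6.10 respectively —
pI values are only comparable within one table. Proteome-wide histograms
use 1-pH-unit bins over 3–12, which resolves the bimodal, mostly acidic
distribution typical of seed proteomes.

## 2-D gel spot differentials

Spot percentages make gels comparable by scaling each replicate column to
sum to 100 (idempotent; an all-zero column is an error naming the column).
The filter's criteria and defaults (`fold_min = 2`, `alpha = 0.05`,
`floor_frac = 0.25`) are described in the README. Choices worth recording:

- **t-test** — two-sided Student's with pooled variance (df = n1+n2−2) on
  replicate spot percentages; conventional in commercial gel-analysis
  software and defensible at n = 2+2. Welch is available by flag. Degenerate
  inputs: both groups constant and equal → p = 1; constant but separated →
  p = 0 sentinel.
- **Fold-change convention** — signed ratio of group 2 relative to group 1:
  ≥ +1 when higher, ≤ −1 when lower (negated inverse ratio), so |fold| ≥ 1
  always and swapping groups flips the sign. A zero mean on one side yields
  ±∞ and excludes the spot from ratio-based criteria with a flag rather
  than propagating an infinite ratio.
- **Abundance floor** — "the highest spot percentage" is interpreted as the
  highest *cell* (subgroup × group) mean; every reported reference row
  clears 0.25 × 100/1267 ≈ 0.0197 under this reading.
- **Multiple testing** — none is applied in the filter (matching practice
  for these gel studies); a Benjamini–Hochberg column is emitted for
  information only.
- **Reporting** — fold change displayed at 1 decimal and p at 3, with full
  precision retained internally. Note that re-deriving fold changes from
  cell means that were themselves rounded to 3 decimals can shift the
  1-decimal fold by up to ~0.25 when means are of order 0.003–0.01.

## Presence–absence and GO trends

The acceptance rule — (≥ 2 matching peptides OR score > 40) AND p < 0.05,
with strict inequalities — is applied per record; records within one
(cultivar, stage) cell are union-merged because low-abundance proteins are
detected stochastically across replicates and injections. Union merging is
idempotent, order-independent and monotone under added records.

GO ranking counts, per term and per cell, the distinct present proteins
annotated to the term, and ranks terms by the maximum count over cells
(threshold configurable; 10 by default for plots). The trend test compares
per-(stage, cultivar) counts between the first and last three stages of the
six-stage series (n = 6 per side with two cultivars pooled; per-cultivar
mode available), flagging terms with two-sided t-test p < 0.05 and fold
change > 2. A zero mean on one side gives an infinite fold, which passes the
fold criterion — the degenerate "present early, absent late" histone-like
pattern is exactly the signal of interest. An optional seventh, mature-only
time point can be carried in the matrix but is excluded from early/late
grouping by default.

## Extracted-ion chromatograms

Windows are ± tol ppm computed **relative to the target m/z** (not the peak)
with **inclusive** boundaries — both conventions must be fixed for
reproducible edge behaviour; at 872.4482 and 20 ppm the half-window is
0.01745 Th. Every scan contributes exactly one point (zero if no peak in
window), so EICs are additive over disjoint peak subsets and monotone in
tolerance. Presence requires ≥ 3 consecutive points (default) above the
intensity threshold; calls are monotone in both thresholds. MGF
(TITLE/RTINSECONDS/PEPMASS blocks, read and written via pyteomics) is the
supported dialect.

## Synthetic data: what it emulates, and what it does not

All generators draw from named substreams of a single seed
(`numpy.random.Generator` spawned per stream; no global state), so the same
configuration reproduces byte-identical files.

- **Proteome** — random canonical-alphabet proteins (80–300 aa) plus a
  deterministic planted structure: a 2S-albumin-like allergen precursor
  assembled from tryptic segments (a 19-residue signal peptide, four
  specific peptides — two of them genuine pecan allergen marker sequences so
  their ions can be planted in peak lists — and two peptides shared with a
  constructed homolog). Its zero-missed digest yields exactly 7 length-7–25
  candidates: 1 signal-overlapping, 2 non-specific, 4 markers. The scaffold
  contains no K/R–P junction, so the count is invariant to the proline-rule
  setting.
- **Spot tables** — log-normal baselines (σ = 1; silver-stain densities are
  positive and right-skewed), default 1267 spots mirroring the reference
  gel series, with 12 planted multiplicative shifts (default fold 4, up
  with probability 0.75 to mimic the excess of increasing spots during
  maturation) applied to the late stage in both cultivars, and per-replicate
  log-normal noise with CV 0.1 (mean-corrected). Real silver-stain noise
  levels are study-specific; the CV is a free parameter, not calibrated.
  Fold changes are planted only on spots whose baseline clears the
  abundance floor (baseline ≥ 0.3 × mean), because a spot below the floor
  criterion is unrecoverable by construction and reported differential
  spots all clear it — ground truth must determine the expected output.
- **Detections** — six stages × two cultivars × three replicates; ~10% of
  proteins are "early-only" (detected in the first three stages only, the
  histone-like pattern), annotated to the planted trend GO terms; the rest
  are stable and annotated to the remaining terms. Each present cell has a
  guaranteed passing record in replicate 1, further replicates pass with
  probability 0.8, and sub-threshold noise records (1 peptide, score < 40,
  p > 0.05) are sprinkled into absent cells to exercise the acceptance rule
  and union merging.
- **Peak lists** — `n_scans` centroided scans over `rt_range` minutes; each
  planted ion is a Gaussian elution peak (σ = 2 scan intervals, amplitude
  10^5.5–10^6.5) with per-scan m/z jitter uniform within ±15 ppm of theory —
  always inside a ±20 ppm search window, mirroring the up-to-~18 ppm
  observed deviations of the reference ions. Decoys are kept > 50 ppm from
  every target. No profile-mode spectra, isotope envelopes or chimeric
  peaks are simulated.

Consequently, passing tests demonstrate the *logic* of the pipeline — the
filters, merges and window arithmetic recover planted truth — not its
robustness to gel warping, spot co-migration, missing-value structure,
retention-time drift or isotope interference, none of which the generator
models.

## Problem sizes used in automated checks

Simulation-based checks use 50 tables of 200 spots (recovery) and 50 tables
of 300 spots (null calibration), 40-protein detection sets, and 120-scan
peak lists; these sizes give stable rates (SE of the null fraction
≈ 0.0018 at 15,000 tests) while keeping the whole suite interactive.

## Known limitations

- The t-test at n = 2+2 replicate gels has little power and its p-values
  are sensitive to the pooled-variance assumption; the filter's strength
  comes from the conjunction of criteria, not the test alone.
- Substring specificity screening is only as good as the homolog set
  supplied; absence from the provided homologs is not proteome-wide
  uniqueness.
- GO ranking does no enrichment testing and no ontology-graph propagation;
  counts are over the supplied flat annotations.
- pI calculation ignores post-translational charge modifications and folded-
  state effects; values are comparable only within one pKa table.
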