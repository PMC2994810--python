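# Methods

This note documents the models behind `eggdosage`: what is simulated,
what is assumed, which knobs matter, and what the tests do and do not
demonstrate about real plasma data.

## The measurement model

### Methylation index (MI)

A CpG *unit* is one or more CpG sites reported as one scalar by a
mass-spectrometric methylation assay.  Its MI is estimated either from
the methylated/unmethylated peak-height pair,
`MI = h_m / (h_m + h_u)`, or from bisulfite-sequencing clones,
`MI = methylated clones / total clones`.  Both estimators are bounded in
[0, 1] and invariant to uniform intensity scaling.  Peak heights below a
configurable noise floor (default 0, i.e. off) are zeroed before the
ratio; a unit with no remaining signal is an undefined measurement, not
an MI of 0.  Per-site disaggregation of a multi-site unit is not
attempted.

### Molecule pools and digestion

Plasma DNA is represented at molecule level: counts keyed by marker
(`VAPA_APCDD1` chr18, `ZFY` chrY, `ACTB` control), origin (fetal /
maternal) and the methylation pattern over the enzyme sites spanned by
each amplicon (5, 0 and 4 sites respectively).  Digestion by HpaII +
HinP1I cuts each **unmethylated** site independently with probability
`efficiency`; a molecule stays amplifiable iff no site is cut, so the
expected surviving fraction of a molecule with `u` unmethylated sites is
`(1 − efficiency)^u`.  Methylated sites are never cut.  `efficiency`
defaults to 1.0 — the wet protocol treats digestion as complete and the
β-actin control enforces it — and sub-unit values exist only for
robustness studies; mock digestion is `efficiency = 0`.  Cuts at
distinct sites are assumed independent, ignoring processivity and
steric effects, which is harmless at efficiency 1.

### qPCR and digital PCR

qPCR copy numbers convert through a log-linear standard curve
`Cq = intercept + slope·log10(copies)` (the study's assays: slopes
−3.77/−3.53, intercepts 39.7/38.9 Cq) and are censored — not zeroed —
below the limit of detection (3 copies/reaction), so diagnostics can
distinguish "no signal" from "weak signal".  Amplification kinetics and
Cq noise are not modelled.

Digital PCR partitions a diluted sample over the wells of a plate;
per-well template counts are Poisson, a well is positive iff it holds
≥ 1 template, and the plug-in MLE `m = −ln(1 − p̂)` with
`molecules = m · wells` inverts the occupancy map exactly.  No
small-plate bias correction is applied (the measured relative bias of
the estimator is < 2% for m in [0.05, 1] on 384 wells).  A fully
positive plate raises a saturation error rather than returning an
infinite estimate.  Usable wells default to 376 (a 384-well plate minus
8 no-template controls); the duplex readout of the two markers is
modelled as independent plates.

### Dilution to a common reference concentration

Before counting, each sample is scaled so the reference marker (ZFY)
averages `target_m` templates per well (default 0.5, the classic
one-template-per-two-wells design point).  Scaling is deterministic and
common to all markers, so the EGG ratio's expectation is unchanged.
The pipeline caps the factor at 1 — plasma cannot be concentrated — so
template-limited samples run at their native concentration, which is
why simulated cohorts sit near m ≈ 0.08 rather than at 0.5, matching
the concentrations reported for the clinical cohort.

### EGG ratio, reference interval, classification

`R = VAPA-APCDD1 molecules / ZFY molecules` per sample; a sample with
zero reference molecules (female fetus, assay failure) is unanalyzable
and never coerced to 0 or ∞.  The euploid reference interval is
mean ± 1.96·SD of **raw** ratios (sample SD, n−1), matching the
symmetric construction used clinically even though ratios are
right-skewed; a log-scale variant is available but off by default.
Classification is strictly `R > upper`; below-lower ratios are flagged
for QC but called negative.  Note an intrinsic property of the
construction: recomputed on its own cohort, the interval leaves ≈ 5% of
euploid ratios outside asymptotically, so "specificity = 1" is only a
fixed-seed spot check, never a guarantee.

### Rank tests

Mann-Whitney (marker-selection ploidy comparison, cohort comparison)
and Wilcoxon signed-rank (postpartum clearance) are implemented
in-package as exact enumerations at small n (all group labelings up to
8 per arm; all 2^n sign assignments up to 15 pairs), with tie-corrected,
continuity-corrected normal approximations beyond.  Two-sided p is
twice the smaller tail, capped at 1; all-tied data give p = 1.  scipy's
implementations serve as an independent cross-check in the test suite
only, so no external package's conventions leak into reported values.

## The synthetic cohort generator

The generator emulates the study conditions:

| parameter | default | rationale |
|---|---|---|
| cohort sizes | 27 euploid + 9 trisomy 18 | the clinical study design (male fetuses) |
| fetal fraction | Uniform(0.03, 0.10) | the accepted 3–10% range in maternal plasma |
| genome equivalents / aliquot | 500 | free parameter; 500 GE at 3–10% fetal fraction reproduces the reported reference-marker concentrations (median m ≈ 0.05–0.08/well) without dilution |
| chr18 copies | 2 euploid / 3 trisomy | the dosage signal (1.5-fold) |
| ZFY copies per fetal genome | 1 | single Y chromosome |
| fetal per-site methylation | 0.9 | placental bisulfite clones are predominantly, not fully, methylated |
| maternal marker methylation | 0.0 | blood-cell MI ≈ 0.00–0.05; a nonzero "leak" is exposed to stress specificity |
| digestion efficiency | 1.0 | complete digestion, enforced by controls |
| wells per assay | 376 | 384 − 8 NTCs |

Molecule counts are Poisson (sampling of cell-free DNA into an
aliquot), with fetal chr18-marker mean `ff·GE·copies`, ZFY mean
`ff·GE`, and a maternal background of `(1−ff)·GE·2` unmethylated marker
molecules and no ZFY.  Sites on fetal molecules are methylated
independently.  MI panels draw per-unit normals clamped to [0, 1] —
the simplest model consistent with means and CVs; a logit-normal would
avoid boundary mass and is a documented swap point.  One cohort seed
expands into per-sample child seeds via `SeedSequence` spawn keys, so
enlarging a cohort never perturbs existing samples.

**What is not emulated:** gestational-age trends in fetal DNA
concentration, fragment-length distributions, Epityper mass-spectrum
physics (peak heights are summarized directly as MI), PCR inhibition,
cross-channel competition in the duplex assay, and any methylation
heterogeneity between placentas beyond the per-unit normal model.
Passing tests therefore show that the *analysis* is correct under its
stated statistical model, not that the assay would perform identically
on clinical plasma; cohort-specific clinical numbers (reference-interval
endpoints, per-trimester detection rates) are deliberately not
reproduction targets.

## The synthetic study design (`design.py`)

The screening panel plants a known truth: 370 CpG units in 26 loci, of
which 40 units in 8 loci (19/5/4/4/3/2/2/1 per locus) satisfy the
tissue-contrast criteria by construction (blood MI 0.05 ± 0.02,
placenta 0.85 ± 0.05), while failing units either carry high blood
methylation (0.45) or insufficient contrast (difference 0.25).  The
margins are many sampling SDs wide, so recovery of the planted set is
deterministic in practice and any deviation indicates a defect in the
criteria logic, not noise.  Six quantitative assays over the five top
loci are tuned to median inter-individual CVs spanning ~8–38% (means
lowered for high-CV assays so clamping at 1 cannot reorder them), and
four candidate regions carry 5/3/1/1 planted enzyme sites within the
±100 bp window plus out-of-window decoys.

## Numerical choices

* Criteria comparisons are inclusive with a 1e-12 epsilon so that
  boundary cases (e.g. a difference of exactly 0.50 computed as
  0.7 − 0.2 in floating point) pass as intended.
* "Within 100 bp of a region" means the region extended by 100 bp on
  each side, endpoints inclusive; site positions are compared in the
  region's own frame (the scanner's 0-based offsets get a +1 shift).
* Coordinates: 1-based inclusive in tabular/region objects (genome-
  browser text convention), 0-based half-open in BED; converters live at
  the I/O boundary only.
* Tissue summary for the criteria is the median across samples (equal
  to the mean at the n = 2 screening stage); CVs use the n−1 SD.
* Marker selection ties break by lowest median CV, then lexical assay
  id.  N bases never match an enzyme motif.
* Units with mean placental MI of 0 have no defined CV and are dropped
  from assay medians with a warning; units present in one tissue only
  are flagged unevaluable and excluded from pass counts.

## Problem sizes

Monte-Carlo checks are sized so their standard error sits well inside
the asserted tolerance: the dosage-fold experiment uses 20 000 samples
per arm (fold SE ≈ 0.5% against a 2% check — the per-sample ratio is
heavy-tailed at tens of reference molecules, so smaller cohorts leave
the check underpowered); digital-PCR estimator checks use 10⁴ replicate
plates; digestion oracles use 10⁴ molecules.  The whole suite runs in
well under a minute on one CPU.

## Known limitations

* Sensitivity/specificity of the default 36-sample cohort fluctuate
  seed to seed; only their monotone behaviour (in fetal fraction,
  template input, well count) and the large-replicate dosage fold are
  stable claims.
* The normal-approximation branches of the rank tests are adequate for
  the moderate n they serve but are not high-precision tail
  approximations.
* The digestion model treats sites independently and ignores partial
  amplicon damage; at the default efficiency of 1 these simplifications
  have no effect.
* Female-fetus analysis (paternal autosomal markers as the genetic
  reference) is out of scope.
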