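# eggdosage

Epigenetic-genetic (EGG) chromosome-dosage analysis for the noninvasive
detection of fetal trisomy 18 (Edwards syndrome) from maternal plasma —
implemented as a tested, reproducible pipeline over synthetic cohorts.

## The problem and who this is for

Cell-free DNA in a pregnant woman's plasma is mostly maternal; only a
low fraction (typically 3–10%) is fetal, released by the placenta.
Detecting that a fetus carries three copies of chromosome 18 instead of
two therefore requires either counting millions of molecules, or
targeting fetal-specific species directly.  The EGG approach does the
latter with two fetal-specific markers:

* an **epigenetic marker** on chr18 — an intergenic region between the
  *VAPA* and *APCDD1* genes that is hypermethylated in the placenta but
  unmethylated in maternal blood cells.  Digesting plasma DNA with the
  methylation-sensitive enzymes HpaII (CCGG) and HinP1I (GCGC) destroys
  the unmethylated maternal copies; only molecules methylated at **all
  five** enzyme sites spanned by the amplicon remain amplifiable, and
  those are fetal;
* a **genetic marker** on a reference chromosome — *ZFY* on chrY, absent
  from the mother entirely (male fetuses).

Both species are counted absolutely by digital PCR: the sample is
partitioned into the wells of a 384-well plate and the number of
template molecules is recovered from the positive-well count by Poisson
correction,

```
m = −ln(1 − positive wells / total wells),    molecules = m × wells.
```

The per-sample **EGG ratio** is

```
R = (digestion-resistant VAPA-APCDD1 molecules) / (ZFY molecules),
```

which tracks the fetal chr18 : chrY copy ratio — about 2 for a euploid
male fetus, about 3 (a 1.5-fold increase) under trisomy 18.  A sample is
called trisomy 18 when R exceeds the upper bound of a euploid
**reference interval**, mean ± 1.96 SD of the euploid cohort's ratios.

Upstream of the assay, the package implements the full marker-selection
cascade from a per-CpG-unit methylation-index (MI) panel: tissue
contrast criteria (blood MI ≤ 0.20 and placenta−blood difference
≥ 0.50), ranking of assays by the median inter-individual coefficient of
variation of placental MI, a euploid-vs-trisomy placental methylation
comparison (exact Mann-Whitney), and an enzyme-site scan that picks the
candidate region with the most HpaII/HinP1I sites within 100 bp.

The intended audience is anyone studying cell-free DNA diagnostics or
methylation-sensitive restriction assays who wants an executable,
testable model of this analysis rather than a description of it.

## Layout

* `src/eggdosage/` — the library: synthetic cohort generation
  (`synthetic`, `design`), MI quantification (`methylation`), marker
  selection (`selection`), digestion and qPCR (`assays`), digital PCR
  (`digital`), the EGG classifier (`classifier`), exact rank tests
  (`stats`), file formats (`io`), and the end-to-end pipeline
  (`pipeline`, `experiments`).
* `analysis/` — numbered drivers that tell the story:
  `01_simulate_study_inputs.py`, `02_select_marker.py`,
  `03_plasma_validation.py`, `04_egg_cohort_analysis.py`.  Each writes
  its tables under `results/`.
* `eggdosage` console script — `simulate-cohort`, `select-markers`,
  `scan-sites`, `digest`, `digital-count`, `egg-classify`, `evaluate`,
  `run-all`.

## Worked example

Running the four analysis drivers in order:

```bash
python analysis/01_simulate_study_inputs.py
python analysis/02_select_marker.py
python analysis/03_plasma_validation.py
python analysis/04_egg_cohort_analysis.py
```

prints (abridged):

```
criteria #1/#2: 40 of 370 CpG units pass, located in 8 loci
median inter-individual CV per assay: {'MAT.18.0094.1': 0.089, ..., 'TAS.18.1887.1': 0.382}
  4 most stable assays kept: ['MAT.18.0094.1', 'MAT.18.0094.2', 'MAT.18.0071.3', 'MAT.18.0097.2']
  MAT.18.0094.1: 7 sites in sequence, 5 within 100 bp of the region
selected marker region: MAT.18.0094.1 (most enzyme sites -> most complete removal of unmethylated maternal DNA)

Wilcoxon signed-rank (10 pairs): W+ = 55, two-sided p = 0.00195 (exact enumeration)
=> the marker is cleared after delivery: it is fetal-specific in plasma

analyzed 36 samples (27 euploid, 9 trisomy 18); 0 excluded by controls
median reference-marker concentration m: 0.077 (euploid), 0.069 (trisomy) per well
EGG ratios, euploid vs trisomy 18: medians 0.97 vs 1.88 (Mann-Whitney two-sided p = 0.000485)
euploid reference interval (mean ± 1.96 SD): 0.24-1.84
classification vs karyotype: 5/9 trisomy 18 and 2/27 euploid above the cutoff
  -> sensitivity 55.6%, specificity 92.6%
dosage-fold experiment (2000 samples per arm): mean trisomy / mean euploid EGG ratio = 1.519
```

Reading the numbers: the selection cascade recovers the planted 40
passing CpG units in 8 loci and picks the chr18 intergenic region with 5
enzyme sites; the digestion-resistant marker vanishes after delivery
(exact paired p ≈ 0.002), confirming fetal specificity; and on a small
36-sample cohort at realistic template numbers (tens of reference
molecules per aliquot, m ≈ 0.07–0.08 per well) the trisomy ratios sit
clearly above the euploid ratios, while single-sample classification at
these molecule counts remains noisy — the dosage fold across large
replicate cohorts converges to the theoretical 3/2.

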