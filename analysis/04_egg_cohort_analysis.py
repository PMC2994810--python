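#!/usr/bin/env python
"""EGG chromosome-dosage analysis of the simulated maternal-plasma cohort.

Runs the full pipeline on the default study cohort (27 euploid + 9
trisomy-18 male-fetus pregnancies): digestion, dilution to a common
ZFY reference concentration, digital PCR with Poisson correction, the
chr18/chrY EGG ratio, the euploid mean±1.96 SD reference interval, and
classification.  Also compares the two ploidy groups (Mann-Whitney) and
reports the large-replicate dosage-fold experiment, whose expectation
is the 3/2 chr18 copy ratio.  Outputs to ``results/egg/``.
"""

from pathlib import Path

from eggdosage.experiments import dosage_fold_experiment
from eggdosage.pipeline import PipelineConfig, run_end_to_end
from eggdosage.stats import mann_whitney_u

SEED = 2026
OUT = Path("results/egg")


def main() -> None:
    config = PipelineConfig(seed=SEED)
    result = run_end_to_end(config, OUT)
    egg = result.egg_results

    eu = egg.query("status == 'euploid'")
    tr = egg.query("status == 'trisomy18'")
    print(f"analyzed {len(egg)} samples ({len(eu)} euploid, {len(tr)} trisomy 18); "
          f"{len(result.excluded)} excluded by controls")
    print(f"median reference-marker concentration m: "
          f"{eu.m_zfy.median():.3f} (euploid), {tr.m_zfy.median():.3f} (trisomy) per well")

    mw = mann_whitney_u(eu.egg_ratio.to_numpy(), tr.egg_ratio.to_numpy())
    print(f"EGG ratios, euploid vs trisomy 18: medians {eu.egg_ratio.median():.2f} vs "
          f"{tr.egg_ratio.median():.2f} (Mann-Whitney two-sided p = {mw.pvalue:.3g})")

    interval = result.interval
    print(f"euploid reference interval (mean ± 1.96 SD): "
          f"{interval.lower:.2f}-{interval.upper:.2f}")
    perf = result.performance
    print(f"classification vs karyotype: {perf.tp}/{perf.tp + perf.fn} trisomy 18 and "
          f"{perf.fp}/{perf.fp + perf.tn} euploid above the cutoff "
          f"-> sensitivity {100 * perf.sensitivity:.1f}%, "
          f"specificity {100 * perf.specificity:.1f}%")

    fold = dosage_fold_experiment(n_per_group=2000, seed=SEED)
    print(f"dosage-fold experiment (2000 samples per arm): mean trisomy / mean euploid "
          f"EGG ratio = {fold.fold:.3f} (expected 3/2 from the chr18 copy numbers)")
    print(f"outputs written to {result.outdir}")


if __name__ == "__main__":
    main()
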