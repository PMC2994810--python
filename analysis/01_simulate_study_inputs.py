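#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes every input the downstream analyses consume to ``results/inputs/``:
the 370-CpG-unit two-tissue screening panel (2 placentas vs 2 maternal
blood cell samples), the 10-placenta panel of the six quantitative
methylation assays, matched 6 euploid vs 6 trisomy-18 placenta panels,
the four candidate marker-region sequences with planted HpaII/HinP1I
sites, and the plasma-cohort configuration (27 euploid + 9 trisomy-18
male-fetus pregnancies).  All generation is deterministic given SEED.
"""

from pathlib import Path

from eggdosage import io
from eggdosage.design import cv_assay_models, cv_panel, marker_region_designs, screening_panel
from eggdosage.pipeline import PipelineConfig
from eggdosage.synthetic import generate_tissue_panel

SEED = 2026
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    panel, expected = screening_panel(seed=SEED)
    io.write_table(panel, OUT / "screening_panel.tsv")
    print(f"screening panel: {panel.unit_id.nunique()} CpG units, "
          f"{panel.locus_id.nunique()} loci, planted pass-set of "
          f"{sum(len(v) for v in expected.values())} units in {len(expected)} loci")

    cv = cv_panel(seed=SEED)
    io.write_table(cv, OUT / "cv_panel.tsv")
    print(f"CV panel: {cv.assay_id.nunique()} assays x 10 placentas")

    # euploid vs trisomy-18 placenta panels share the same methylation model:
    # trisomy is a copy-number change, not a methylation change
    frames = []
    for group, offset in (("euploid", 0), ("trisomy18", 1000)):
        for assay_id, model in cv_assay_models():
            sub = generate_tissue_panel(model, n_placenta=6, n_blood=1, seed=SEED + offset)
            sub = sub[sub.tissue == "placenta"].copy()
            sub["assay_id"] = assay_id
            sub["group"] = group
            frames.append(sub)
    import pandas as pd
    ploidy = pd.concat(frames, ignore_index=True)
    io.write_table(ploidy, OUT / "ploidy_panel.tsv")
    print("ploidy panel: 6 euploid vs 6 trisomy-18 placentas per assay")

    designs = marker_region_designs()
    io.write_fasta({d.region.assay_id: d.sequence(seed=SEED) for d in designs},
                   OUT / "marker_regions.fa")
    io.write_regions([d.region for d in designs], OUT / "marker_regions.tsv",
                     dialect="onebased")
    print(f"marker regions: {len(designs)} candidate sequences with planted enzyme sites")

    config = PipelineConfig(seed=SEED)
    io.save_config_dict(config.to_dict(), OUT / "pipeline_config.json")
    print(f"plasma cohort config: {config.cohort.n_euploid} euploid + "
          f"{config.cohort.n_trisomy} trisomy-18, fetal fraction "
          f"{config.cohort.fetal_fraction_range[0]:.0%}-{config.cohort.fetal_fraction_range[1]:.0%}")


if __name__ == "__main__":
    main()
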