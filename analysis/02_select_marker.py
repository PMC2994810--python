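#!/usr/bin/env python
"""Run the marker-selection cascade on the simulated study inputs.

Reads the panels written by 01_simulate_study_inputs.py and applies, in
order: the two tissue-contrast criteria (blood MI <= 0.20, placenta-blood
difference >= 0.50), the inter-individual CV ranking of the quantitative
assays, the euploid-vs-trisomy placental methylation comparison
(Mann-Whitney), and the HpaII/HinP1I enzyme-site scan of the candidate
regions.  Writes the per-stage tables and the final selection report to
``results/selection/``.
"""

import json
from pathlib import Path

from eggdosage import io
from eggdosage.selection import (
    EnzymeSite,
    RegionCandidate,
    apply_criteria,
    compare_ploidy_groups,
    count_sites_near_region,
    rank_assays_by_cv,
    scan_enzyme_sites,
    select_marker,
)

IN = Path("results/inputs")
OUT = Path("results/selection")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # stage 1: tissue-contrast criteria on the screening panel
    panel = io.read_table(IN / "screening_panel.tsv",
                          required=("sample_id", "tissue", "locus_id", "unit_id", "mi"))
    units, locus_counts = apply_criteria(panel)
    io.write_table(units, OUT / "criteria_per_unit.tsv")
    n_pass, n_loci = int(units.passes.sum()), int((locus_counts > 0).sum())
    print(f"criteria #1/#2: {n_pass} of {int(units.evaluable.sum())} CpG units pass, "
          f"located in {n_loci} loci")
    print("  passing units per locus:",
          {k: int(v) for k, v in locus_counts.sort_values(ascending=False).items()})

    # stage 2: inter-individual stability of the quantitative assays
    cv = io.read_table(IN / "cv_panel.tsv", required=("sample_id", "unit_id", "assay_id", "mi"))
    unit_cv, assay_cv, top4 = rank_assays_by_cv(cv, k=4)
    io.write_table(unit_cv, OUT / "unit_cv.tsv")
    io.write_table(assay_cv.reset_index(), OUT / "assay_median_cv.tsv")
    print("median inter-individual CV per assay:",
          {k: round(v, 3) for k, v in assay_cv.items()})
    print(f"  4 most stable assays kept: {top4}")

    # stage 3: placental methylation unaffected by ploidy
    ploidy = io.read_table(IN / "ploidy_panel.tsv",
                           required=("unit_id", "assay_id", "group", "mi"))
    ploidy = ploidy[ploidy.assay_id.isin(top4)]
    comparison = compare_ploidy_groups(
        ploidy[ploidy.group == "euploid"], ploidy[ploidy.group == "trisomy18"]
    )
    io.write_table(comparison, OUT / "ploidy_comparison.tsv")
    n_sig = int((comparison.p < 0.05).sum())
    print(f"euploid vs trisomy-18 placentas: {n_sig} of {len(comparison)} CpG units "
          f"differ at p<0.05 (methylation is ploidy-independent when ~none do)")

    # stage 4: enzyme-site density around each candidate region
    sequences = io.read_fasta(IN / "marker_regions.fa")
    regions = {r.assay_id: r for r in io.read_regions(IN / "marker_regions.tsv", dialect="onebased")}
    candidates = []
    for assay_id, seq in sequences.items():
        sites = scan_enzyme_sites(seq)
        # scanner positions are 0-based; shift into the regions' 1-based frame
        shifted = [EnzymeSite(s.enzyme, s.position + 1, s.motif) for s in sites]
        n = count_sites_near_region(regions[assay_id], shifted, window=100)
        cv_score = float(assay_cv.get(assay_id)) if assay_id in assay_cv.index else None
        candidates.append(RegionCandidate(regions[assay_id], n, cv_score))
        print(f"  {assay_id}: {len(sites)} sites in sequence, {n} within 100 bp of the region")
    winner = select_marker(candidates)
    print(f"selected marker region: {winner.assay_id} "
          f"(most enzyme sites -> most complete removal of unmethylated maternal DNA)")

    report = {
        "criteria_passing_units": n_pass,
        "criteria_passing_loci": n_loci,
        "passing_units_per_locus": {k: int(v) for k, v in locus_counts.items()},
        "assay_median_cv": {k: float(v) for k, v in assay_cv.items()},
        "selected_assays": top4,
        "ploidy_comparison_significant_units": n_sig,
        "site_counts": {c.region.assay_id: c.site_count for c in candidates},
        "selected_marker": winner.assay_id,
    }
    (OUT / "selection_report.json").write_text(json.dumps(report, indent=2) + "\n")


if __name__ == "__main__":
    main()
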