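"""Marker-selection cascade: criteria, CV ranking, ploidy test, site scan."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from eggdosage.design import marker_region_designs, screening_panel
from eggdosage.selection import (
    AssayRegion,
    EnzymeSite,
    RegionCandidate,
    SelectionCriteria,
    apply_criteria,
    compare_ploidy_groups,
    count_sites_near_region,
    rank_assays_by_cv,
    scan_enzyme_sites,
    select_marker,
)
from eggdosage.stats import mann_whitney_u


def _panel(rows):
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "locus_id", "unit_id", "mi"])


def _unit_rows(unit_id, blood, placenta, locus="L1"):
    rows = []
    for i, v in enumerate(blood):
        rows.append((f"B{i}", "maternal_blood_cells", locus, unit_id, v))
    for i, v in enumerate(placenta):
        rows.append((f"P{i}", "placenta", locus, unit_id, v))
    return rows


class TestApplyCriteria:
    @pytest.mark.parametrize(
        "blood,placenta,passes",
        [
            (0.15, 0.80, True),   # clears both thresholds
            (0.20, 0.70, True),   # both comparisons inclusive at the boundary
            (0.25, 0.95, False),  # blood too methylated (criterion #1)
            (0.05, 0.50, False),  # contrast too small (criterion #2)
            (0.10, 0.60, True),   # diff exactly 0.50
        ],
    )
    def test_threshold_logic(self, blood, placenta, passes):
        table, _ = apply_criteria(_panel(_unit_rows("u1", [blood] * 2, [placenta] * 2)))
        assert bool(table.loc[0, "passes"]) is passes

    def test_summary_is_median_across_samples(self):
        # blood median 0.1 passes even though one sample is high
        table, _ = apply_criteria(
            _panel(_unit_rows("u1", [0.05, 0.10, 0.9], [0.8, 0.85, 0.9]))
        )
        assert bool(table.loc[0, "passes"])

    def test_single_tissue_unit_unevaluable(self):
        rows = _unit_rows("u1", [0.05] * 2, [0.9] * 2)
        rows += [("P0", "placenta", "L1", "u2", 0.9), ("P1", "placenta", "L1", "u2", 0.8)]
        table, counts = apply_criteria(_panel(rows))
        u2 = table[table.unit_id == "u2"].iloc[0]
        assert not u2["evaluable"] and not u2["passes"]
        assert counts["L1"] == 1

    def test_extreme_panels_pass_all_or_none(self):
        rows = []
        for u in range(10):
            rows += _unit_rows(f"u{u}", [0.05] * 3, [0.85] * 3)
        table, _ = apply_criteria(_panel(rows))
        assert table["passes"].all()
        rows = []
        for u in range(10):
            rows += _unit_rows(f"u{u}", [0.5] * 3, [0.95] * 3)
        table, _ = apply_criteria(_panel(rows))
        assert not table["passes"].any()

    def test_planted_pass_set_recovered_exactly(self):
        """On the synthetic 370-unit screen the known pass-set is recovered."""
        panel, expected = screening_panel(seed=123)
        table, counts = apply_criteria(panel)
        recovered = set(table.loc[table["passes"], "unit_id"])
        assert recovered == set().union(*expected.values())
        assert int(table["passes"].sum()) == 40
        assert int((counts > 0).sum()) == 8
        assert counts.max() == 19  # the chr18 intergenic locus dominates


class TestCvRanking:
    def test_zero_variance_gives_zero_cv(self):
        df = pd.DataFrame(
            {"sample_id": ["P1", "P2", "P3"], "locus_id": "L", "unit_id": "u",
             "mi": [0.8, 0.8, 0.8]}
        )
        unit_cv, assay_cv, _ = rank_assays_by_cv(df, k=1)
        assert unit_cv.cv.iloc[0] == 0.0

    def test_hand_computed_cv(self):
        # sample SD (n-1) 0.35355 over mean 0.75
        df = pd.DataFrame(
            {"sample_id": ["P1", "P2"], "locus_id": "L", "unit_id": "u", "mi": [0.5, 1.0]}
        )
        unit_cv, _, _ = rank_assays_by_cv(df, k=1)
        assert unit_cv.cv.iloc[0] == pytest.approx(0.47140452, rel=1e-6)

    def test_lowest_median_cv_selected_and_order_invariant(self):
        rows = []
        for assay, mis in [("A", [0.8, 0.9, 1.0]), ("B", [0.5, 0.9, 1.0])]:
            for i, mi in enumerate(mis):
                rows.append({"sample_id": f"P{i}", "locus_id": assay, "unit_id": f"{assay}.u",
                             "assay_id": assay, "mi": mi})
        df = pd.DataFrame(rows)
        _, _, top = rank_assays_by_cv(df, k=1)
        assert top == ["A"]
        _, _, top_rev = rank_assays_by_cv(df.iloc[::-1].reset_index(drop=True), k=1)
        assert top_rev == top

    def test_zero_mean_unit_excluded_with_warning(self):
        df = pd.DataFrame(
            {"sample_id": ["P1", "P2", "P1", "P2"], "locus_id": "L",
             "unit_id": ["u0", "u0", "u1", "u1"], "mi": [0.0, 0.0, 0.5, 0.7]}
        )
        with pytest.warns(UserWarning, match="mean MI = 0"):
            unit_cv, _, _ = rank_assays_by_cv(df, k=1)
        assert list(unit_cv.unit_id) == ["u1"]

    def test_single_sample_rejected(self):
        df = pd.DataFrame({"sample_id": ["P1"], "locus_id": "L", "unit_id": "u", "mi": [0.5]})
        with pytest.raises(ValueError, match=">= 2 placenta samples"):
            rank_assays_by_cv(df)


class TestPloidyComparison:
    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"unit_id": "u", "mi": [0.7, 0.8, 0.9]})
        out = compare_ploidy_groups(df, df.copy())
        assert out.p.iloc[0] == 1.0

    def test_separated_groups_exact_enumeration(self):
        eu = pd.DataFrame({"unit_id": "u", "mi": [1.0, 2.0, 3.0]})
        tr = pd.DataFrame({"unit_id": "u", "mi": [4.0, 5.0, 6.0]})
        out = compare_ploidy_groups(eu, tr)
        assert out.u.iloc[0] == 0.0
        assert out.p.iloc[0] == pytest.approx(0.1)

    def test_rank_invariance_under_scaling(self):
        eu = pd.DataFrame({"unit_id": "u", "mi": [0.1, 0.4, 0.2]})
        tr = pd.DataFrame({"unit_id": "u", "mi": [0.3, 0.5, 0.6]})
        base = compare_ploidy_groups(eu, tr)
        doubled = compare_ploidy_groups(eu.assign(mi=eu.mi * 2), tr.assign(mi=tr.mi * 2))
        assert base.u.iloc[0] == doubled.u.iloc[0]
        assert base.p.iloc[0] == doubled.p.iloc[0]

    def test_matches_scipy_exact_test(self, rng):
        """Independent cross-check of the in-package exact U test."""
        for _ in range(20):
            x = rng.random(5)
            y = rng.random(6) + rng.normal(0, 0.5)
            ours = mann_whitney_u(x, y)
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_small_group_excluded_with_warning(self):
        eu = pd.DataFrame({"unit_id": "u", "mi": [0.1]})
        tr = pd.DataFrame({"unit_id": "u", "mi": [0.3, 0.5]})
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = compare_ploidy_groups(eu, tr)
        assert out.empty


def brute_force_scan(seq):
    """O(n*m) substring oracle for the enzyme-site scanner."""
    hits = set()
    for motif, enzyme in [("CCGG", "HpaII"), ("GCGC", "HinP1I")]:
        for i in range(len(seq)):
            if seq[i : i + 4] == motif:
                hits.add((enzyme, i))
    return hits


class TestEnzymeScan:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AACCGGTT", {("HpaII", 2)}),
            ("GCGCGC", {("HinP1I", 0), ("HinP1I", 2)}),  # overlap counted
            ("ATATATAT", set()),
            ("CCGG", {("HpaII", 0)}),
            ("CCGCGG", set()),
            ("NCGG", set()),  # N never matches
        ],
    )
    def test_known_sequences(self, seq, expected):
        assert {(s.enzyme, s.position) for s in scan_enzyme_sites(seq)} == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            scan_enzyme_sites("ACGTX")

    @settings(max_examples=300, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
    def test_agrees_with_brute_force_oracle(self, seq):
        found = {(s.enzyme, s.position) for s in scan_enzyme_sites(seq)}
        assert found == brute_force_scan(seq)


class TestSiteCountingAndSelection:
    region = AssayRegion("a1", "L1", "chr18", 200, 300)

    def site(self, pos):
        return EnzymeSite("HpaII", pos, "CCGG")

    def test_window_boundaries(self):
        assert count_sites_near_region(self.region, [self.site(150)]) == 1
        assert count_sites_near_region(self.region, [self.site(100)]) == 1  # inclusive
        assert count_sites_near_region(self.region, [self.site(99)]) == 0
        assert count_sites_near_region(self.region, [self.site(400)]) == 1
        assert count_sites_near_region(self.region, [self.site(401)]) == 0

    def test_planted_design_counts(self):
        """Round trip: planted in-window sites are counted, decoys are not."""
        expected = {"MAT.18.0094.1": 5, "MAT.18.0094.2": 3,
                    "MAT.18.0071.3": 1, "MAT.18.0097.2": 1}
        for design in marker_region_designs():
            seq = design.sequence(seed=11)
            sites = [
                EnzymeSite(s.enzyme, s.position + 1, s.motif)  # into the 1-based frame
                for s in scan_enzyme_sites(seq)
            ]
            n = count_sites_near_region(design.region, sites, window=100)
            assert n == expected[design.region.assay_id]

    def test_select_marker_takes_max_count_then_cv_then_id(self):
        regions = {
            name: AssayRegion(name, name, "chr18", 1, 100)
            for name in ("A", "B", "C", "D")
        }
        candidates = [
            RegionCandidate(regions["A"], 5, 0.10),
            RegionCandidate(regions["B"], 3, 0.05),
            RegionCandidate(regions["C"], 1, 0.01),
            RegionCandidate(regions["D"], 1, 0.02),
        ]
        assert select_marker(candidates).assay_id == "A"
        # count tie broken by CV
        tie = [RegionCandidate(regions["A"], 3, 0.38), RegionCandidate(regions["B"], 3, 0.08)]
        assert select_marker(tie).assay_id == "B"
        # full tie broken lexically
        lex = [RegionCandidate(regions["B"], 3, 0.1), RegionCandidate(regions["A"], 3, 0.1)]
        assert select_marker(lex).assay_id == "A"
        assert select_marker([candidates[0]]).assay_id == "A"
        with pytest.raises(ValueError):
            select_marker([])
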