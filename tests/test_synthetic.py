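"""Synthetic tissue panels, plasma pools, and planted marker sequences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eggdosage.pools import FETAL, MATERNAL, VAPA_APCDD1, ZFY
from eggdosage.selection import scan_enzyme_sites
from eggdosage.synthetic import (
    EUPLOID,
    TRISOMY18,
    PlasmaCohortConfig,
    TissueMethylationModel,
    generate_cohort,
    generate_marker_sequence,
    generate_plasma_sample,
    generate_tissue_panel,
)


def model(p_mean=0.8, p_sd=0.05, b_mean=0.05, b_sd=0.02, n_units=4):
    return TissueMethylationModel(
        locus_id="LOC.18.TEST",
        unit_ids=tuple(f"u{i}" for i in range(n_units)),
        placenta_mean_mi=(p_mean,) * n_units,
        placenta_sd_mi=(p_sd,) * n_units,
        blood_mean_mi=(b_mean,) * n_units,
        blood_sd_mi=(b_sd,) * n_units,
    )


class TestTissuePanel:
    def test_zero_variance_reproduces_means_exactly(self):
        panel = generate_tissue_panel(model(p_sd=0.0, b_sd=0.0), 3, 3, seed=1)
        placenta = panel[panel.tissue == "placenta"]
        blood = panel[panel.tissue == "maternal_blood_cells"]
        assert (placenta.mi == 0.8).all()
        assert (blood.mi == 0.05).all()

    def test_same_seed_same_panel(self):
        a = generate_tissue_panel(model(), 5, 5, seed=42)
        b = generate_tissue_panel(model(), 5, 5, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = generate_tissue_panel(model(), 5, 5, seed=43)
        assert not a.mi.equals(c.mi)

    def test_growing_the_panel_keeps_earlier_samples(self):
        small = generate_tissue_panel(model(), 3, 3, seed=7)
        large = generate_tissue_panel(model(), 6, 6, seed=7)
        merged = large.merge(small, on=["sample_id", "tissue", "unit_id"], suffixes=("", "_small"))
        assert np.allclose(merged.mi, merged.mi_small)

    def test_empirical_means_match_model(self):
        """Monte-Carlo check against the stated sampling distribution."""
        n = 200
        panel = generate_tissue_panel(model(0.8, 0.05, 0.05, 0.02, n_units=1), n, n, seed=3)
        for tissue, mean, sd in [
            ("placenta", 0.8, 0.05),
            ("maternal_blood_cells", 0.05, 0.02),
        ]:
            mis = panel[panel.tissue == tissue].mi
            assert abs(mis.mean() - mean) < 3 * sd / np.sqrt(n) + 0.005  # clamp bias margin

    def test_mi_always_in_unit_interval(self):
        panel = generate_tissue_panel(model(0.95, 0.3, 0.02, 0.3), 50, 50, seed=5)
        assert panel.mi.between(0, 1).all()

    def test_nonfinite_model_rejected(self):
        with pytest.raises(ValueError):
            model(p_mean=float("nan"))
        with pytest.raises(ValueError):
            model(p_sd=-0.1)
        with pytest.raises(ValueError):
            generate_tissue_panel(model(), 0, 3, seed=1)


class TestPlasmaSample:
    def test_zero_fetal_fraction_gives_no_fetal_molecules(self):
        config = PlasmaCohortConfig(fetal_fraction_range=(0.0, 0.0))
        pool = generate_plasma_sample(config, EUPLOID, seed=1)
        assert pool.total(ZFY) == 0
        assert pool.total(VAPA_APCDD1, origin=FETAL) == 0
        assert pool.total(VAPA_APCDD1, origin=MATERNAL) > 0

    def test_full_methylation_gives_all_methylated_patterns(self):
        config = PlasmaCohortConfig(per_site_methylation=1.0)
        pool = generate_plasma_sample(config, TRISOMY18, seed=2)
        fetal = {
            pattern
            for (mk, og, pattern) in pool.entries
            if mk == VAPA_APCDD1 and og == FETAL
        }
        assert fetal == {(True,) * 5}

    def test_maternal_background_is_unmethylated_without_leak(self):
        pool = generate_plasma_sample(PlasmaCohortConfig(), EUPLOID, seed=3)
        maternal = {
            pattern
            for (mk, og, pattern) in pool.entries
            if mk == VAPA_APCDD1 and og == MATERNAL
        }
        assert maternal == {(False,) * 5}

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            generate_plasma_sample(PlasmaCohortConfig(), "mosaic", seed=1)

    def test_determinism(self):
        a = generate_plasma_sample(PlasmaCohortConfig(), EUPLOID, seed=9)
        b = generate_plasma_sample(PlasmaCohortConfig(), EUPLOID, seed=9)
        assert a == b

    def test_poisson_means_and_dosage_structure(self):
        """Empirical fetal counts match Poisson expectations; trisomy/euploid
        fetal chr18-marker means approach the 3/2 copy-number ratio."""
        config = PlasmaCohortConfig(
            fetal_fraction_range=(0.05, 0.05), genome_equivalents=400.0,
            per_site_methylation=1.0,
        )
        n_rep = 1000
        fetal_marker = {EUPLOID: [], TRISOMY18: []}
        zfy = []
        for i in range(n_rep):
            for status in (EUPLOID, TRISOMY18):
                pool = generate_plasma_sample(config, status, seed=10_000 + i)
                fetal_marker[status].append(pool.total(VAPA_APCDD1, origin=FETAL))
            zfy.append(pool.total(ZFY))
        lam_eu = 0.05 * 400 * 2
        lam_zfy = 0.05 * 400
        se_eu = np.sqrt(lam_eu / n_rep)
        assert abs(np.mean(fetal_marker[EUPLOID]) - lam_eu) < 3 * se_eu
        assert abs(np.mean(zfy) - lam_zfy) < 3 * np.sqrt(lam_zfy / n_rep)
        fold = np.mean(fetal_marker[TRISOMY18]) / np.mean(fetal_marker[EUPLOID])
        assert fold == pytest.approx(1.5, rel=0.05)

    def test_cohort_sample_seeds_are_stable_under_growth(self):
        small = generate_cohort(PlasmaCohortConfig(n_euploid=3, n_trisomy=2, seed=5))
        large = generate_cohort(PlasmaCohortConfig(n_euploid=6, n_trisomy=4, seed=5))
        by_id = {s.sample_id: s for s in large}
        for s in small:
            assert by_id[s.sample_id].pool == s.pool

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PlasmaCohortConfig(fetal_fraction_range=(0.5, 0.1))
        with pytest.raises(ValueError):
            PlasmaCohortConfig(per_site_methylation=1.5)
        with pytest.raises(ValueError):
            PlasmaCohortConfig(chr18_copies_euploid=3, chr18_copies_trisomy=3)


class TestMarkerSequence:
    def test_planted_sites_recovered_exactly(self):
        seq = generate_marker_sequence(200, hpaii_positions=(0, 50, 120), hinp1i_positions=(80, 160), seed=1)
        assert len(seq) == 200
        sites = scan_enzyme_sites(seq)
        assert {(s.enzyme, s.position) for s in sites} == {
            ("HpaII", 0), ("HpaII", 50), ("HpaII", 120), ("HinP1I", 80), ("HinP1I", 160),
        }

    def test_no_planted_sites_scans_empty(self):
        seq = generate_marker_sequence(300, seed=2)
        assert scan_enzyme_sites(seq) == []

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError):
            generate_marker_sequence(100, hpaii_positions=(10,), hinp1i_positions=(12,))
        with pytest.raises(ValueError):
            generate_marker_sequence(100, hpaii_positions=(98,))

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), start=st.integers(0, 60))
    def test_roundtrip_property(self, seed, start):
        """Any non-overlapping planting is recovered by an exhaustive scan."""
        hpaii = (start, start + 8)
        hinp1i = (start + 16,)
        seq = generate_marker_sequence(90, hpaii, hinp1i, seed=seed)
        found = {(s.enzyme, s.position) for s in scan_enzyme_sites(seq)}
        assert found == {("HpaII", start), ("HpaII", start + 8), ("HinP1I", start + 16)}
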