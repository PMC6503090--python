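"""Design fidelity, factor-model calibration and generator determinism."""

import io

import numpy as np
import pytest

from barotrend.cohort import (
    GROUPS, PROXIES, CorrelationCalibration, FactorEffects,
    default_calibration, default_design, generate_cohort, read_cohort_csv,
    sample_single_factor, solve_ansi_component_loading, write_cohort_csv,
)
from barotrend.errors import CalibrationError, ConfigurationError
from barotrend.robust import pearson, wincorr


class TestDefaultDesign:
    def test_stratum_counts_and_total(self):
        d = default_design()
        counts = [s.count for s in d.strata]
        assert counts == [84, 158, 282, 254, 144, 167, 65]
        assert d.total_n == 1154

    def test_group_counts(self):
        assert default_design().group_counts == {"Nt": 778, "preHt": 144, "Ht": 232}

    def test_female_cell_total(self):
        d = default_design()
        female = sum(n for (g, _, _), n in d.cell_counts.items() if g == "F")
        assert female == 646

    def test_sap_intervals_ordered_and_grouped(self):
        d = default_design()
        uppers = [s.upper for s in d.strata]
        lowers = [s.lower for s in d.strata]
        assert lowers == sorted(lowers) and uppers == sorted(uppers)
        # group boundaries at 130 and 140 mmHg
        for s in d.strata:
            if s.upper <= 130:
                assert s.group == "Nt"
            elif s.upper <= 140:
                assert s.group == "preHt"
            else:
                assert s.group == "Ht"

    def test_inconsistent_cells_rejected(self):
        d = default_design()
        bad = dict(d.cell_counts)
        bad[("F", "17-30", "Nt")] += 1
        with pytest.raises(ConfigurationError):
            type(d)(strata=d.strata, cell_counts=bad)


class TestSingleFactor:
    def test_unit_loading_duplicates_alpha(self, rng):
        m = sample_single_factor([1.0], 100, rng)
        np.testing.assert_allclose(m[:, 1], m[:, 0], rtol=0, atol=1e-12)
        assert pearson(m[:, 0], m[:, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_zero_loading_independent(self, rng):
        m = sample_single_factor([0.0], 200_000, rng)
        assert abs(pearson(m[:, 0], m[:, 1])) < 0.01

    def test_loading_recovered_at_large_n(self, rng):
        m = sample_single_factor([0.6], 1_000_000, rng)
        assert pearson(m[:, 0], m[:, 1]) == pytest.approx(0.6, abs=0.01)

    def test_cross_loading_product_structure(self, rng):
        m = sample_single_factor([0.8, -0.5], 1_000_000, rng)
        assert pearson(m[:, 1], m[:, 2]) == pytest.approx(0.8 * -0.5, abs=0.01)

    def test_invalid_loading_rejected(self, rng):
        with pytest.raises(CalibrationError):
            sample_single_factor([1.2], 10, rng)


class TestGenerateCohort:
    def test_counts_match_design_exactly(self, small_design, flat_calibration):
        for seed in (0, 1, 2):
            coh = generate_cohort(
                small_design, FactorEffects.none(), flat_calibration, 0.0, seed=seed
            )
            assert coh["group"].value_counts().to_dict() == {
                "Nt": 40, "preHt": 30, "Ht": 30
            }

    def test_default_design_preht_has_144(self, paper_cohort):
        assert (paper_cohort["group"] == "preHt").sum() == 144
        assert (paper_cohort["stratum"] == "Nt3").sum() == 282

    def test_sap_consistent_with_stratum(self, paper_cohort):
        sap = paper_cohort["sap_clinic"]
        grp = paper_cohort["group"]
        assert (sap[grp == "Nt"] < 130).all()
        assert sap[grp == "preHt"].between(130, 140, inclusive="left").all()
        assert (sap[grp == "Ht"] >= 140).all()

    def test_deterministic_csv_output(self, small_design, flat_calibration, tmp_path):
        effects = FactorEffects.default()
        buffers = []
        for _ in range(2):
            coh = generate_cohort(small_design, effects, flat_calibration, 0.02, seed=5)
            buf = io.StringIO()
            write_cohort_csv(coh, buf)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]
        p = tmp_path / "c.csv"
        p.write_text(buffers[0])
        rt = read_cohort_csv(p)
        assert len(rt) == small_design.total_n
        assert set(rt["age_class"]) <= {"17-30", "31-49", "50-86"}

    def test_missing_group_calibration_rejected(self, small_design):
        calib = CorrelationCalibration(loadings={"Nt": {"hr": 0.3}})
        with pytest.raises(ConfigurationError):
            generate_cohort(small_design, FactorEffects.none(), calib, 0.0, seed=0)

    def test_calibration_recovery_within_mc_error(self, small_design):
        """Mean sample r over 200 clean cohorts recovers the loading."""
        calib = CorrelationCalibration(loadings={"overall": {"rr_tp": 0.6}})
        effects = FactorEffects.none()
        rs = np.array(
            [
                pearson(c["alpha"], c["rr_tp"])
                for c in (
                    generate_cohort(small_design, effects, calib, 0.0, seed=s)
                    for s in range(200)
                )
            ]
        )
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean() - 0.6) < 3 * se

    def test_contamination_hurts_pearson_more_than_wincorr(self, small_design):
        """|pearson - L| is stochastically larger than |wincorr - L| with outliers."""
        calib = CorrelationCalibration(loadings={"overall": {"rr_tp": 0.6}})
        effects = FactorEffects.none()
        pe, we = [], []
        for s in range(60):
            c = generate_cohort(
                small_design, effects, calib,
                contamination_fraction=0.05, contamination_scale=8.0, seed=1000 + s,
            )
            pe.append(abs(pearson(c["alpha"], c["rr_tp"]) - 0.6))
            we.append(abs(wincorr(c["alpha"], c["rr_tp"], 0.1) - 0.6))
        assert np.mean(pe) > np.mean(we)


class TestAnsiCalibrationSolver:
    def test_monotone_and_sign_symmetric(self):
        l1 = solve_ansi_component_loading(0.3)
        l2 = solve_ansi_component_loading(0.6)
        assert 0 < l1 < l2 < 1
        assert solve_ansi_component_loading(-0.3) == pytest.approx(-l1)

    def test_unattainable_target_rejected(self):
        with pytest.raises(CalibrationError):
            solve_ansi_component_loading(0.995)

    def test_default_calibration_valid(self):
        calib = default_calibration()
        for g in GROUPS:
            vec = calib.loadings_for_group(g)
            assert np.all(np.abs(vec) <= 1)
            assert len(vec) == len(PROXIES)
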