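"""Gating rule table, threshold calibration and surrogate regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mzlspatial as mz
from mzlspatial import gating
from mzlspatial.gating import GatingError


def make_cells(rows):
    """rows: list of (CD4, PD1, FOXP3, Ki67) intensity tuples."""
    df = pd.DataFrame(rows, columns=["CD4", "PD1", "FOXP3", "Ki67"])
    df.insert(0, "cell_id", range(len(df)))
    df.insert(1, "x", np.linspace(0, 10, len(df)))
    df.insert(2, "y", np.linspace(0, 10, len(df)))
    return df


UNIT_THRESH = mz.GatingConfig(
    thresholds={"CD4": 10.0, "PD1": 10.0, "FOXP3": 10.0, "Ki67": 10.0}
)


class TestCalibration:
    def test_reference_quantile_convention(self):
        ref = pd.DataFrame({"PD1": np.arange(1.0, 101.0)})
        cfg = mz.calibrate_pd1_threshold(ref, mz.GatingConfig(reference_quantile=0.05))
        # linear interpolation between order statistics: 5.95
        assert cfg.thresholds["PD1"] == pytest.approx(5.95)

    def test_quantile_limit_is_minimum(self):
        ref = pd.DataFrame({"PD1": np.arange(1.0, 101.0)})
        cfg = mz.calibrate_pd1_threshold(
            ref, mz.GatingConfig(reference_quantile=1e-9)
        )
        assert cfg.thresholds["PD1"] == pytest.approx(1.0)

    def test_degenerate_reference_single_value(self):
        ref = pd.DataFrame({"PD1": [7.0, 7.0, 7.0]})
        for q in (0.05, 0.5, 0.95):
            cfg = mz.calibrate_pd1_threshold(
                ref, mz.GatingConfig(reference_quantile=q)
            )
            assert cfg.thresholds["PD1"] == 7.0

    def test_original_config_unmodified(self):
        ref = pd.DataFrame({"PD1": np.arange(1.0, 101.0)})
        base = mz.GatingConfig()
        mz.calibrate_pd1_threshold(ref, base)
        assert "PD1" not in base.thresholds

    def test_empty_or_zero_reference_rejected(self):
        with pytest.raises(GatingError):
            mz.calibrate_pd1_threshold(pd.DataFrame({"PD1": []}))
        with pytest.raises(GatingError):
            mz.calibrate_pd1_threshold(pd.DataFrame({"PD1": [0.0, 0.0]}))

    def test_bad_quantile_rejected(self):
        with pytest.raises(GatingError):
            mz.GatingConfig(reference_quantile=0.0)

    def test_bimodal_threshold_splits_modes(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.lognormal(1.0, 0.25, 1000), rng.lognormal(4.0, 0.25, 1000)]
        )
        t = gating.bimodal_threshold(vals)
        assert np.exp(2.0) < t < np.exp(3.0)

    def test_unimodal_channel_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(GatingError):
            gating.bimodal_threshold(rng.lognormal(2.0, 0.25, 2000))


class TestRuleTable:
    def test_cd4_pd1hi_foxp3neg_is_tfh(self):
        cells = make_cells([(20.0, 11.0, 1.0, 1.0)])
        calls = mz.gate_cells(cells, UNIT_THRESH)
        assert calls.loc[0, "phenotype"] == "Tfh"

    def test_cd4_pd1lo_foxp3pos_is_treg(self):
        cells = make_cells([(20.0, 2.0, 30.0, 1.0)])
        calls = mz.gate_cells(cells, UNIT_THRESH)
        assert calls.loc[0, "phenotype"] == "Treg"

    def test_cd4_pd1hi_foxp3pos_is_tfr(self):
        cells = make_cells([(20.0, 15.0, 30.0, 1.0)])
        calls = mz.gate_cells(cells, UNIT_THRESH)
        assert calls.loc[0, "phenotype"] == "Tfr"

    def test_all_zero_is_other_without_flags(self):
        cells = make_cells([(0.0, 0.0, 0.0, 0.0)])
        calls = mz.gate_cells(cells, UNIT_THRESH)
        row = calls.loc[0]
        assert row["phenotype"] == "other"
        assert not (row["cd4_pos"] or row["pd1_hi"] or row["foxp3_pos"] or row["ki67_pos"])

    def test_boundary_intensity_is_positive(self):
        cells = make_cells([(10.0, 10.0, 1.0, 10.0)])
        row = mz.gate_cells(cells, UNIT_THRESH).loc[0]
        assert row["phenotype"] == "Tfh" and row["ki67_pos"]

    def test_missing_channel_named_in_error(self):
        cells = make_cells([(1.0, 1.0, 1.0, 1.0)]).drop(columns=["FOXP3"])
        with pytest.raises(GatingError, match="FOXP3"):
            mz.gate_cells(cells, UNIT_THRESH)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.tuples(
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
            st.floats(0, 100, allow_nan=False),
        )
    )
    def test_rule_table_exhaustive_and_exclusive(self, intensities):
        calls = mz.gate_cells(make_cells([intensities]), UNIT_THRESH)
        row = calls.loc[0]
        assert row["phenotype"] in gating.PHENOTYPES
        # phenotype consistent with flags
        if row["phenotype"] == "Tfh":
            assert row["cd4_pos"] and row["pd1_hi"] and not row["foxp3_pos"]
        elif row["phenotype"] == "Tfr":
            assert row["cd4_pos"] and row["pd1_hi"] and row["foxp3_pos"]
        elif row["phenotype"] == "Treg":
            assert row["cd4_pos"] and not row["pd1_hi"] and row["foxp3_pos"]
        else:
            assert not (row["cd4_pos"] and (row["pd1_hi"] or row["foxp3_pos"]))

    def test_gating_pure_function(self):
        _, table = mz.simulate_full_tissue(seed=13)
        cfg = mz.resolve_thresholds(table)
        assert mz.gate_cells(table, cfg).equals(mz.gate_cells(table, cfg))

    def test_raising_tau_pd1_is_monotone(self):
        _, table = mz.simulate_full_tissue(seed=13)
        base = mz.resolve_thresholds(table)
        n_prev = np.inf
        for tau in (5.0, 12.0, 40.0, 200.0):
            calls = mz.gate_cells(table, base.with_threshold("PD1", tau))
            n = int(calls["pd1_hi"].sum())
            assert n <= n_prev
            n_prev = n


class TestSummary:
    def test_subset_fraction_arithmetic(self):
        rows = []
        rows += [(20.0, 15.0, 1.0, 1.0)] * 10  # Tfh
        rows += [(20.0, 1.0, 15.0, 1.0)] * 5  # Treg
        rows += [(20.0, 15.0, 15.0, 1.0)] * 1  # Tfr
        rows += [(20.0, 1.0, 1.0, 1.0)] * 84  # CD4+ other
        calls = mz.gate_cells(make_cells(rows), UNIT_THRESH)
        s = mz.subset_summary(calls)
        assert s["n_cd4"] == 100
        assert s["subset_fraction_of_cd4"] == pytest.approx(0.16)

    def test_zero_cd4_fractions_undefined(self):
        calls = mz.gate_cells(make_cells([(0.0, 0.0, 0.0, 0.0)] * 3), UNIT_THRESH)
        s = mz.subset_summary(calls)
        assert np.isnan(s["subset_fraction_of_cd4"])

    def test_ratio_sentinel_without_foxp3(self):
        calls = mz.gate_cells(make_cells([(20.0, 15.0, 1.0, 1.0)] * 4), UNIT_THRESH)
        s = mz.subset_summary(calls)
        assert np.isinf(s["pd1hi_foxp3_ratio"])

    def test_empty_calls_rejected(self):
        with pytest.raises(GatingError):
            mz.subset_summary(pd.DataFrame())

    def test_roundtrip_fractions_match_generated_mixture(self):
        _, table = mz.simulate_full_tissue(seed=31)
        cfg = mz.resolve_thresholds(table)
        calls = mz.gate_cells(table, cfg)
        s = mz.subset_summary(calls)
        truth = table["true_label"].value_counts()
        cd4_truth = truth["Tfh"] + truth["Treg"] + truth["background"]
        assert s["counts"]["Tfh"] == truth["Tfh"]
        assert s["counts"]["Treg"] == truth["Treg"]
        assert s["n_cd4"] == cd4_truth


class TestSurrogate:
    def _case(self, seed):
        _, table = mz.simulate_full_tissue(seed=seed)
        return mz.gate_cells(table, mz.resolve_thresholds(table))

    def test_identity_counts_give_r2_one(self):
        cases = {f"c{i}": self._case(100 + i) for i in range(3)}
        rep = mz.surrogate_agreement(cases, surrogate="PD1hi", subset="Tfh")
        # with no Tfr and no PD1hi non-CD4 cells the counts are equal
        assert rep["r_squared"] > 0.999

    def test_two_cases_rejected(self):
        cases = {f"c{i}": self._case(200 + i) for i in range(2)}
        with pytest.raises(GatingError):
            mz.surrogate_agreement(cases)

    def test_constant_predictor_flagged(self):
        calls = self._case(300)
        rep = mz.surrogate_agreement({"a": calls, "b": calls, "c": calls})
        assert rep["degenerate"] and np.isnan(rep["r_squared"])

    def test_unknown_population_rejected(self):
        with pytest.raises(GatingError):
            mz.gating.select_population(self._case(301), "nonsense")
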