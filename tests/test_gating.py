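"""Threshold calibration and gating: oracle equivalence, boundaries, typing."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plexquant import (
    CalibrationError,
    NegativeControlRule,
    ThresholdSet,
    assign_cell_type,
    calibrate_panel,
    calibrate_threshold,
    call_positivity,
    select_negative_controls,
)
from plexquant.panel import DEFAULT_PANEL

from conftest import small_config
from plexquant import generate_cells


def _table(intensities: dict[str, list[float]]) -> pd.DataFrame:
    n = len(next(iter(intensities.values())))
    base = {
        "cell_id": [f"c{i}" for i in range(n)],
        "tissue_id": "t1",
        "tissue_role": "test",
        "compartment": "zone",
        "x_um": 0.0,
        "y_um": 0.0,
    }
    return pd.DataFrame({**base, **{m: vals for m, vals in intensities.items()}})


class TestCalibrateThreshold:
    def test_all_zero_background_gives_zero_cutoff(self):
        t = _table({"TIGIT": [0.0] * 50})
        assert calibrate_threshold(t, "TIGIT", set(t["cell_id"])) == 0.0

    def test_sixty_listed_values_cutoff_is_their_max(self):
        t = _table({"TIGIT": [float(i) for i in range(1, 61)]})
        assert calibrate_threshold(t, "TIGIT", set(t["cell_id"])) == 60.0

    def test_deterministic_on_repeat(self):
        t = _table({"TIGIT": list(np.random.default_rng(0).lognormal(0, 1, 80))})
        ids = set(t["cell_id"])
        assert calibrate_threshold(t, "TIGIT", ids) == calibrate_threshold(t, "TIGIT", ids)

    @pytest.mark.parametrize("n", [10, 49, 201, 400])
    def test_window_enforced(self, n):
        t = _table({"TIGIT": [1.0] * n})
        with pytest.raises(CalibrationError, match=r"\[50, 200\]"):
            calibrate_threshold(t, "TIGIT", set(t["cell_id"]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=50, max_size=200))
    def test_matches_brute_force_max(self, values):
        t = _table({"TIGIT": values})
        oracle = max(values)  # independent brute-force maximum
        assert calibrate_threshold(t, "TIGIT", set(t["cell_id"])) == oracle


class TestSelectNegativeControls:
    def _gated_table(self, n_pos: int, n_neg: int = 300) -> pd.DataFrame:
        cd20 = [10.0] * n_pos + [0.5] * n_neg
        tigit = [1.0] * (n_pos + n_neg)
        return _table({"CD20": cd20, "TIGIT": tigit})

    def test_full_eligibility_takes_all_gated_cells(self):
        t = self._gated_table(n_pos=200)
        th = ThresholdSet(cutoffs={"CD20": 5.0})
        rule = NegativeControlRule("CD20")
        ids = select_negative_controls(t, "TIGIT", rule, max_n=200, seed=3, thresholds=th)
        assert len(ids) == 200
        assert set(ids) == set(t.loc[t["CD20"] > 5.0, "cell_id"])

    def test_too_few_eligible_cells_raises(self):
        t = self._gated_table(n_pos=40)
        th = ThresholdSet(cutoffs={"CD20": 5.0})
        with pytest.raises(CalibrationError, match="larger input region"):
            select_negative_controls(t, "TIGIT", NegativeControlRule("CD20"), seed=0, thresholds=th)

    def test_same_seed_same_ids(self):
        t = self._gated_table(n_pos=500)
        th = ThresholdSet(cutoffs={"CD20": 5.0})
        rule = NegativeControlRule("CD20")
        a = select_negative_controls(t, "TIGIT", rule, max_n=100, seed=9, thresholds=th)
        b = select_negative_controls(t, "TIGIT", rule, max_n=100, seed=9, thresholds=th)
        c = select_negative_controls(t, "TIGIT", rule, max_n=100, seed=10, thresholds=th)
        assert a == b
        assert a != c

    def test_exclusion_marker_removes_contaminants(self):
        t = self._gated_table(n_pos=200)
        # make 10 of the gated cells CD3-bright (mislabelled T cells)
        t["CD3"] = 0.5
        t.loc[t.index[:10], "CD3"] = 20.0
        th = ThresholdSet(cutoffs={"CD20": 5.0, "CD3": 5.0})
        rule = NegativeControlRule("CD20", exclude_markers=("CD3",))
        ids = select_negative_controls(t, "TIGIT", rule, max_n=200, seed=1, thresholds=th)
        assert set(ids).isdisjoint(set(t["cell_id"].iloc[:10]))


class TestCallPositivity:
    def _pheno(self, intensity: float, cutoff: float) -> bool:
        markers = {m: [1.0] for m in DEFAULT_PANEL.markers}
        markers["TIGIT"] = [intensity]
        t = _table(markers)
        th = ThresholdSet(cutoffs={m: 100.0 for m in DEFAULT_PANEL.markers})
        th.cutoffs["TIGIT"] = cutoff
        return bool(call_positivity(t, th)["TIGIT_pos"].iloc[0])

    def test_intensity_equal_to_cutoff_is_negative(self):
        assert self._pheno(intensity=2.0, cutoff=2.0) is False

    def test_intensity_epsilon_above_cutoff_is_positive(self):
        assert self._pheno(intensity=2.0 + 1e-12, cutoff=2.0) is True

    def test_zero_thresholds_call_everything_positive(self):
        markers = {m: [0.5, 3.0] for m in DEFAULT_PANEL.markers}
        t = _table(markers)
        th = ThresholdSet(cutoffs={m: 0.0 for m in DEFAULT_PANEL.markers})
        pheno = call_positivity(t, th)
        assert all(pheno[f"{m}_pos"].all() for m in DEFAULT_PANEL.markers)

    def test_monotonicity_raising_intensity_never_unflips(self):
        """Raising a marker intensity can only turn a negative call positive."""
        rng = np.random.default_rng(42)
        markers = {m: list(rng.lognormal(0, 1, 50)) for m in DEFAULT_PANEL.markers}
        t = _table(markers)
        th = ThresholdSet(cutoffs={m: 1.0 for m in DEFAULT_PANEL.markers})
        before = call_positivity(t, th)
        bumped = t.copy()
        bumped["TIGIT"] = bumped["TIGIT"] + rng.random(50) * 5
        after = call_positivity(bumped, th)
        flipped_off = before["TIGIT_pos"] & ~after["TIGIT_pos"]
        assert not flipped_off.any()

    def test_checkpoint_state_consistent_with_booleans(self):
        markers = {m: [1.0, 1.0, 1.0, 1.0] for m in DEFAULT_PANEL.markers}
        markers["TIGIT"] = [5.0, 5.0, 0.1, 0.1]
        markers["PD-1"] = [5.0, 0.1, 5.0, 0.1]
        t = _table(markers)
        th = ThresholdSet(cutoffs={m: 2.0 for m in DEFAULT_PANEL.markers})
        pheno = call_positivity(t, th)
        assert list(pheno["checkpoint_state"]) == [
            "TIGIT+PD1+", "TIGIT+PD1-", "TIGIT-PD1+", "TIGIT-PD1-",
        ]


def _oracle_cell_type(calls: dict[str, bool]) -> str:
    """Independent statement of the precedence rule."""
    order = [
        ("FOXP3", "FOXP3_Treg"), ("CD8", "CD8_T"), ("CD4", "CD4_T"), ("CD3", "CD3_T"),
        ("CD20", "CD20_B"), ("CD56", "CD56_NK"), ("CD11c", "CD11c_DC"), ("CD68", "CD68_Mac"),
    ]
    for marker, label in order:
        if calls[marker]:
            return label
    return "other"


class TestAssignCellType:
    def test_treg_takes_precedence_over_helper_markers(self):
        df = pd.DataFrame({f"{m}_pos": [m in ("CD3", "CD4", "FOXP3")] for m in DEFAULT_PANEL.lineage_markers})
        assert assign_cell_type(df)["cell_type"].iloc[0] == "FOXP3_Treg"

    def test_all_negative_is_other(self):
        df = pd.DataFrame({f"{m}_pos": [False] for m in DEFAULT_PANEL.lineage_markers})
        assert assign_cell_type(df)["cell_type"].iloc[0] == "other"

    def test_double_positive_cd4_cd8_resolves_to_cd8(self):
        df = pd.DataFrame({f"{m}_pos": [m in ("CD3", "CD4", "CD8")] for m in DEFAULT_PANEL.lineage_markers})
        assert assign_cell_type(df)["cell_type"].iloc[0] == "CD8_T"

    def test_full_enumeration_matches_oracle(self):
        """All 2^8 lineage-call combinations agree with the stated precedence."""
        combos = list(itertools.product([False, True], repeat=8))
        df = pd.DataFrame(
            {f"{m}_pos": [c[i] for c in combos] for i, m in enumerate(DEFAULT_PANEL.lineage_markers)}
        )
        got = assign_cell_type(df)["cell_type"]
        expected = [
            _oracle_cell_type(dict(zip(DEFAULT_PANEL.lineage_markers, c))) for c in combos
        ]
        assert list(got) == expected


class TestGatingFaithfulness:
    def test_truth_positive_cells_called_positive_on_separated_mixtures(self):
        """With positive and background components ≥3 log-sds apart, the
        calibrated cutoff recovers >95% of truth-positive cells."""
        cfg = small_config(seed=6, n_cells=4000, tigit_fraction=0.5)
        sim = generate_cells(cfg)
        th = calibrate_panel(sim.cells, seed=6)
        pheno = call_positivity(sim.cells, th)
        m = sim.cells.merge(pheno, on="cell_id").merge(sim.truth, on="cell_id")
        truth_pos = m["true_TIGIT_pos"].astype(bool)
        recall = m.loc[truth_pos, "TIGIT_pos"].mean()
        assert recall > 0.95
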