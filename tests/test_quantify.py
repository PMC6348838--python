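"""Relative expression, ratios, coexpression, densities, summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from plexquant import (
    GeometryError,
    InsufficientCellsError,
    ReferenceSpec,
    SpotGeometry,
    UndefinedReferenceError,
    coexpression_fractions,
    density,
    density_per_0p1mm2,
    positivity_fraction,
    relative_expression,
    summarize_compartments,
    tigit_pd1_ratio,
)


def _cells(tigit, pd1=None, **ids):
    n = len(tigit)
    return pd.DataFrame(
        {
            "cell_id": ids.get("cell_id", [f"c{i}" for i in range(n)]),
            "tissue_id": ids.get("tissue_id", ["t"] * n),
            "tissue_role": ids.get("tissue_role", ["test"] * n),
            "compartment": ids.get("compartment", ["z"] * n),
            "x_um": 0.0,
            "y_um": 0.0,
            "TIGIT": tigit,
            "PD-1": pd1 if pd1 is not None else tigit,
        }
    )


class TestRelativeExpression:
    def test_identity_population_is_100(self):
        c = _cells([1.0, 2.0, 5.0])
        assert relative_expression(c, c, "TIGIT") == 100.0

    def test_direct_arithmetic(self):
        test = _cells([50.0, 50.0])
        ref = _cells([200.0, 200.0])
        assert relative_expression(test, ref, "TIGIT") == pytest.approx(25.0)

    def test_empty_test_set_rejected(self):
        c = _cells([1.0])
        with pytest.raises(InsufficientCellsError):
            relative_expression(c.iloc[:0], c, "TIGIT")

    def test_zero_reference_mean_is_undefined_not_infinite(self):
        test = _cells([1.0])
        ref = _cells([0.0, 0.0])
        with pytest.raises(UndefinedReferenceError):
            relative_expression(test, ref, "TIGIT")

    def test_scale_invariance(self):
        """Multiplying all intensities by any c > 0 leaves RE unchanged."""
        rng = np.random.default_rng(0)
        test = _cells(rng.lognormal(1, 0.5, 40))
        ref = _cells(rng.lognormal(2, 0.5, 40))
        base = relative_expression(test, ref, "TIGIT")
        for c in (1e-3, 7.3, 1e4):
            scaled_t, scaled_r = test.copy(), ref.copy()
            scaled_t["TIGIT"] *= c
            scaled_r["TIGIT"] *= c
            assert relative_expression(scaled_t, scaled_r, "TIGIT") == pytest.approx(base, rel=1e-12)


class TestRatio:
    def test_balanced_expression_gives_unity(self):
        assert tigit_pd1_ratio(100.0, 100.0) == 1.0

    @pytest.mark.parametrize("re_t,re_p,expected", [(80.0, 40.0, 2.0), (30.0, 40.0, 0.75)])
    def test_arithmetic(self, re_t, re_p, expected):
        assert tigit_pd1_ratio(re_t, re_p) == pytest.approx(expected)

    def test_zero_pd1_is_undefined(self):
        with pytest.raises(UndefinedReferenceError):
            tigit_pd1_ratio(50.0, 0.0)


class TestCoexpression:
    def _pheno(self, t_flags, p_flags):
        return pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(len(t_flags))],
             "TIGIT_pos": t_flags, "PD-1_pos": p_flags}
        )

    def test_saturation(self):
        r = coexpression_fractions(self._pheno([True] * 5, [True] * 5))
        assert (r.frac_tigit_pos_that_are_pd1_pos, r.frac_pd1_pos_that_are_tigit_pos) == (1.0, 1.0)

    def test_counting_oracle(self):
        # 10 TIGIT+ of which 7 PD-1+; 8 PD-1+ of which 7 TIGIT+.
        t = [True] * 10 + [False] * 1 + [False] * 9
        p = [True] * 7 + [False] * 3 + [True] * 1 + [False] * 9
        r = coexpression_fractions(self._pheno(t, p))
        assert r.n_tigit_pos == 10 and r.n_pd1_pos == 8 and r.n_double_pos == 7
        assert r.frac_tigit_pos_that_are_pd1_pos == pytest.approx(0.7)
        assert r.frac_pd1_pos_that_are_tigit_pos == pytest.approx(0.875)
        assert r.n_double_pos <= min(r.n_tigit_pos, r.n_pd1_pos)

    def test_empty_conditional_is_undefined_not_zero(self):
        r = coexpression_fractions(self._pheno([True, False], [False, False]))
        assert r.frac_pd1_pos_that_are_tigit_pos is None
        assert r.frac_tigit_pos_that_are_pd1_pos == 0.0

    def test_scope_restricts_the_population(self):
        pheno = self._pheno([True, True, False], [True, False, False])
        scoped = coexpression_fractions(pheno, scope=pd.Series([True, False, False]))
        assert scoped.n_tigit_pos == 1 and scoped.frac_tigit_pos_that_are_pd1_pos == 1.0


class TestPositivityFraction:
    def _pheno(self, types, flags):
        return pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(len(types))],
             "cell_type": types, "TIGIT_pos": flags}
        )

    def test_all_positive(self):
        p = self._pheno(["CD4_T"] * 4, [True] * 4)
        assert positivity_fraction(p, "CD4_T", "TIGIT") == 1.0

    def test_counting(self):
        p = self._pheno(["CD4_T"] * 100, [True] * 47 + [False] * 53)
        assert positivity_fraction(p, "CD4_T", "TIGIT") == pytest.approx(0.47)

    def test_absent_type_is_undefined(self):
        p = self._pheno(["CD8_T"], [True])
        assert positivity_fraction(p, "CD56_NK", "TIGIT") is None


class TestDensity:
    def test_spot_area_closed_form(self):
        g = SpotGeometry(0.6)
        assert g.area_mm2 == pytest.approx(math.pi * 0.3**2, rel=1e-12)

    def test_zero_count_zero_density(self):
        assert density(0, SpotGeometry(0.6)) == 0.0

    def test_standard_spot_conversions(self):
        assert density(80, SpotGeometry(0.6)) == pytest.approx(80 / (math.pi * 0.09), rel=1e-9)
        assert density(80, SpotGeometry(0.6)) == pytest.approx(282.94, abs=0.01)
        assert density(100, SpotGeometry(4.0)) == pytest.approx(100 / (math.pi * 4.0), rel=1e-9)
        assert density(100, SpotGeometry(4.0)) == pytest.approx(7.96, abs=0.01)

    def test_density_linearity(self):
        g = SpotGeometry(1.7)
        assert density(5 * 13, g) == pytest.approx(5 * density(13, g), rel=1e-12)

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(GeometryError):
            SpotGeometry(0.0)

    def test_per_0p1mm2(self):
        assert density_per_0p1mm2(59, 0.1) == pytest.approx(59.0)
        assert density_per_0p1mm2(118, 0.2) == pytest.approx(59.0)
        assert density_per_0p1mm2(0, 0.5) == 0.0
        with pytest.raises(GeometryError):
            density_per_0p1mm2(1, 0.0)


def _summary_fixture():
    """Hand-built table: reference Gcp CD4 cells with known means, one test
    compartment with means exactly half (TIGIT) and a quarter (PD-1)."""
    ref = _cells(
        tigit=[8.0, 12.0],  # mean 10
        pd1=[4.0, 4.0],     # mean 4
        tissue_id=["ref"] * 2,
        tissue_role=["reference"] * 2,
        compartment=["Gcp"] * 2,
        cell_id=["r0", "r1"],
    )
    test = _cells(
        tigit=[5.0, 5.0],   # mean 5 -> RE 50
        pd1=[1.0, 1.0],     # mean 1 -> RE 25
        tissue_id=["t"] * 2,
        tissue_role=["test"] * 2,
        compartment=["zone"] * 2,
        cell_id=["c0", "c1"],
    )
    cells = pd.concat([ref, test], ignore_index=True)
    pheno = pd.DataFrame(
        {"cell_id": cells["cell_id"], "cell_type": ["CD4_T"] * 4,
         "TIGIT_pos": True, "PD-1_pos": True}
    )
    return cells, pheno


class TestSummaries:
    def test_reference_population_is_exactly_100(self):
        cells, pheno = _summary_fixture()
        s = summarize_compartments(cells, pheno).set_index(["tissue_id", "compartment"])
        ref_row = s.loc[("ref", "Gcp")]
        assert ref_row["RE_TIGIT"] == 100.0
        assert ref_row["RE_PD-1"] == 100.0
        assert ref_row["ratio_tigit_pd1"] == 1.0

    def test_hand_arithmetic(self):
        cells, pheno = _summary_fixture()
        s = summarize_compartments(cells, pheno).set_index(["tissue_id", "compartment"])
        row = s.loc[("t", "zone")]
        assert row["mean_raw_TIGIT"] == pytest.approx(5.0)
        assert row["RE_TIGIT"] == pytest.approx(50.0)
        assert row["RE_PD-1"] == pytest.approx(25.0)
        assert row["ratio_tigit_pd1"] == pytest.approx(2.0)
        assert row["n_cells"] == 2 and bool(row["low_n"])

    def test_missing_reference_raises(self):
        cells, pheno = _summary_fixture()
        with pytest.raises(UndefinedReferenceError):
            summarize_compartments(
                cells, pheno, reference_spec=ReferenceSpec(compartment="Gcc")
            )

    def test_scale_invariance_of_summary(self):
        cells, pheno = _summary_fixture()
        base = summarize_compartments(cells, pheno)
        scaled_cells = cells.copy()
        scaled_cells[["TIGIT", "PD-1"]] *= 37.5
        scaled = summarize_compartments(scaled_cells, pheno)
        for col in ("RE_TIGIT", "RE_PD-1", "ratio_tigit_pd1"):
            np.testing.assert_allclose(scaled[col], base[col], rtol=1e-12)

    def test_low_n_flag_respects_threshold(self):
        cells, pheno = _summary_fixture()
        s = summarize_compartments(cells, pheno, min_n=2)
        assert not s["low_n"].any()
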