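"""ILR machinery, stacked mixed model, omnibus test and pattern taxonomy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from timeuse import coda
from timeuse.coda import (
    DEFAULT_SBP,
    build_stacked,
    classify_pattern,
    estimate_compositions,
    fit_interaction_model,
    ilr_inverse,
    ilr_transform,
    omnibus_interaction_test,
    replace_zeros,
    run_characteristic_analysis,
    sbp_basis,
    validate_sbp,
    wald_pvalue,
)

ALT_SBP = ((("mvpa",), ("sleep", "sed", "lpa")),
           (("lpa",), ("sleep", "sed")),
           (("sed",), ("sleep",)))

compositions = st.lists(st.floats(1.0, 1000.0), min_size=4, max_size=4).map(
    lambda p: np.array(p) * (1440.0 / sum(p)))


class TestIlr:
    def test_sbp_validation(self):
        validate_sbp(DEFAULT_SBP)
        validate_sbp(ALT_SBP)
        with pytest.raises(ValueError, match="partition"):
            validate_sbp(((("sleep",), ("sed",)),
                          (("lpa",), ("mvpa",)),
                          (("sleep",), ("lpa",))))
        with pytest.raises(ValueError, match="splits"):
            validate_sbp(DEFAULT_SBP[:2])

    def test_basis_is_orthonormal(self):
        for sbp in (DEFAULT_SBP, ALT_SBP):
            psi = sbp_basis(sbp)
            assert np.allclose(psi @ psi.T, np.eye(3), atol=1e-12)
            assert np.allclose(psi.sum(axis=1), 0.0, atol=1e-12)

    def test_equal_parts_map_to_origin(self):
        comp = np.array([360.0, 360.0, 360.0, 360.0])
        for sbp in (DEFAULT_SBP, ALT_SBP):
            assert np.allclose(ilr_transform(comp, sbp), 0.0, atol=1e-12)
        assert np.allclose(ilr_inverse(np.zeros(3)), comp)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(compositions)
    def test_round_trip(self, comp):
        z = ilr_transform(comp)
        assert np.allclose(ilr_inverse(z), comp, atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(compositions, compositions)
    def test_isometry(self, a, b):
        """Aitchison distance equals Euclidean distance of the ILR images."""
        clr = lambda x: np.log(x) - np.log(x).mean()
        d_ait = np.linalg.norm(clr(a) - clr(b))
        d_ilr = np.linalg.norm(ilr_transform(a) - ilr_transform(b))
        assert d_ilr == pytest.approx(d_ait, abs=1e-9)

    def test_matches_scikit_bio_basis(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        comp = rng.dirichlet([4, 3, 2, 1], size=8)
        assert np.allclose(ilr_transform(comp),
                           skbio_comp.ilr(comp, basis=sbp_basis()), atol=1e-12)

    def test_perturbing_first_balance_only_moves_its_ratio(self, rng):
        z = rng.normal(0, 0.5, 3)
        base = ilr_inverse(z)
        moved = ilr_inverse(z + np.array([0.3, 0.0, 0.0]))
        # balances 2 and 3 are ratios within the waking parts: unchanged
        assert moved[1] / moved[2] == pytest.approx(base[1] / base[2], rel=1e-9)
        assert moved[2] / moved[3] == pytest.approx(base[2] / base[3], rel=1e-9)
        assert moved[0] / moved[1] != pytest.approx(base[0] / base[1], rel=1e-3)

    def test_zero_part_instructs_replacement(self):
        with pytest.raises(ValueError, match="replace_zeros"):
            ilr_transform(np.array([1000.0, 400.0, 40.0, 0.0]))

    def test_replace_zeros_floors_and_conserves(self):
        out = replace_zeros(np.array([1000.0, 400.0, 40.0, 0.0]))
        assert out[3] == 1.0
        assert out.sum() == pytest.approx(1440.0)
        untouched = np.array([600.0, 500.0, 250.0, 90.0])
        assert np.allclose(replace_zeros(untouched), untouched)


class TestStacking:
    def test_six_rows_per_participant(self, small_table):
        stacked = build_stacked(small_table, "sex")
        assert len(stacked.frame) == 6 * len(small_table)
        counts = stacked.frame.groupby("pid").size()
        assert (counts == 6).all()

    def test_continuous_standardized(self, small_table):
        stacked = build_stacked(small_table, "vo2max")
        per_pid = stacked.frame.groupby("pid")["char_value"].first()
        assert per_pid.mean() == pytest.approx(0.0, abs=1e-12)
        assert per_pid.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert stacked.transform is not None

    def test_age_kept_on_raw_scale(self, small_table):
        stacked = build_stacked(small_table, "age")
        assert stacked.display_levels == (9.5, 10.0, 10.5)
        assert stacked.transform is None

    def test_missing_characteristic_reduces_n(self, small_table):
        n_complete = small_table["academic"].notna().sum()
        stacked = build_stacked(small_table, "academic")
        assert len(stacked.frame) == 6 * n_complete

    def test_single_level_categorical_rejected(self, small_table):
        t = small_table.copy()
        t["sex"] = "female"
        with pytest.raises(ValueError, match="fewer than 2"):
            build_stacked(t, "sex")


class TestModel:
    def test_identical_methods_give_null_interaction(self, small_table):
        t = small_table.copy()
        for b in ("sleep", "sed", "lpa", "mvpa"):
            t[f"self_{b}"] = t[f"device_{b}"]
        res = run_characteristic_analysis(t, "sex")
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_df_rule(self, small_table):
        assert run_characteristic_analysis(small_table, "zbmi").df == 3
        edu = run_characteristic_analysis(small_table, "parental_education")
        n_levels = small_table["parental_education"].nunique()
        assert edu.df == 3 * (n_levels - 1)

    def test_omnibus_invariant_to_sbp_choice(self, small_table):
        a = run_characteristic_analysis(small_table, "vo2max", sbp=DEFAULT_SBP)
        b = run_characteristic_analysis(small_table, "vo2max", sbp=ALT_SBP)
        assert b.chi2 == pytest.approx(a.chi2, rel=1e-2)

    def test_estimates_close_to_1440(self, small_table):
        res = run_characteristic_analysis(small_table, "sex")
        sums = res.estimates[list(("sleep", "sed", "lpa", "mvpa"))].sum(axis=1)
        assert np.allclose(sums, 1440.0, atol=1e-6)
        assert set(res.estimates["method"]) == {"device", "self"}

    def test_wald_pvalue_upper_tail(self):
        assert wald_pvalue(0.0, 3) == pytest.approx(1.0)
        assert wald_pvalue(7.8147, 3) == pytest.approx(0.05, abs=1e-4)

    def test_fallback_ladder_reported(self, small_table):
        stacked = build_stacked(small_table, "sex")
        fit = fit_interaction_model(stacked, maxiter=200)
        assert fit.converged
        assert "intercept" in fit.random_structure

    def test_extrapolation_warns(self, small_table):
        stacked = build_stacked(small_table, "vo2max")
        fit = fit_interaction_model(stacked)
        with pytest.warns(UserWarning, match="outside"):
            estimate_compositions(fit, levels=(0.0, 40.0, 400.0))


class TestPatterns:
    def test_rule_examples(self):
        base = np.array([600.0, 500.0, 250.0, 90.0])

        def labels(dd, ds, tol=5.0):
            return classify_pattern(base, base + dd, base, base + ds, tol)

        inverting = labels(np.array([0, 0, 0, 20.0]), np.array([0, 0, 0, -15.0]))
        assert inverting["mvpa"] == "inverting"
        assert inverting["sleep"] == "isomorphic"
        same = labels(np.array([30.0, 0, 0, 0]), np.array([30.0, 0, 0, 0]))
        assert same["sleep"] == "isomorphic"
        conv = labels(np.array([0, 40.0, 0, 0]), np.array([0, 10.0, 0, 0]))
        assert conv["sed"] == "converging"
        div = labels(np.array([0, 10.0, 0, 0]), np.array([0, 40.0, 0, 0]))
        assert div["sed"] == "diverging"

    def test_tolerance_absorbs_display_rounding(self):
        base = np.array([600.0, 500.0, 250.0, 90.0])
        out = classify_pattern(base, base + 4.0, base, base - 4.0, tolerance=5.0)
        assert all(v == "isomorphic" for v in out.values())
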