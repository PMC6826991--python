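"""Interaction scoring: reference summaries, special-value substitution,
shift-corrected dose regression, stratified z-scores, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenomiq.interaction import (
    DoseProfile,
    build_profiles,
    classify,
    compute_reference_stats,
    score_all,
    score_interaction,
    standardize,
    substitute_ymax,
)

GEM = "gemcitabine"
DOSES = np.array([0.0, 5.0, 10.0, 20.0, 30.0])


def make_cpp_table(rows):
    """rows: (plate, row, col, strain, dose, K, r, L, no_growth)."""
    recs = []
    for plate, r_, c, strain, dose, K, rr, L, ng in rows:
        recs.append(dict(plate=plate, row=r_, col=c, strain=strain, drug=GEM,
                         dose=dose, K=K, r=rr, L=L, rss=0.0, converged=True,
                         no_growth=ng))
    return pd.DataFrame(recs)


def make_profile(y_l, y_k=None, no_growth=None, strain="yko", cls="knockout"):
    n = len(DOSES)
    y = {
        "K": np.asarray(y_k if y_k is not None else [100.0] * n, dtype=float),
        "r": np.full(n, 0.3),
        "L": np.asarray(y_l, dtype=float),
    }
    return DoseProfile(
        strain=strain, strain_class=cls, culture="a:0:0", drug=GEM,
        doses=DOSES.copy(), y=y,
        no_growth=np.asarray(no_growth if no_growth is not None else [False] * n),
    )


def flat_ref_stats(r_l=0.0, r_k=100.0, ymax_l=1e6):
    """ReferenceStats with constant reference means across doses."""
    rows = []
    for d in DOSES:
        rows.append(
            (f"p_d{list(DOSES).index(d)}", 0, 0, "REF", d, r_k, 0.3, r_l, False)
        )
        rows.append(
            (f"p_d{list(DOSES).index(d)}", 0, 1, "REF", d, r_k, 0.3, r_l, False)
        )
        rows.append(  # one high-L culture defines Y_max
            (f"p_d{list(DOSES).index(d)}", 0, 2, "big", d, r_k, 0.3, ymax_l, False)
        )
    stats = compute_reference_stats(make_cpp_table(rows), GEM)
    return stats


class TestReferenceStats:
    def test_identical_refs_flagged_degenerate(self):
        stats = flat_ref_stats()
        assert stats.degenerate_sd
        np.testing.assert_allclose(stats.r_mean["K"], 100.0)

    def test_ymax_excludes_low_K_cultures(self):
        """Worked example: reference K mean 100, SD 5; cultures with
        (K=95, L=20), (K=99, L=25), (K=70, L=40) give Y_max(L) = 25 because
        K = 70 is below mean - 2 SD = 90."""
        rows = [("p_d0", 0, 0, "REF", 0.0, 95.0, 0.3, 10.0, False),
                ("p_d0", 0, 1, "REF", 0.0, 100.0, 0.3, 10.0, False),
                ("p_d0", 0, 2, "REF", 0.0, 105.0, 0.3, 10.0, False),
                ("p_d0", 1, 0, "m1", 0.0, 95.0, 0.3, 20.0, False),
                ("p_d0", 1, 1, "m2", 0.0, 99.0, 0.3, 25.0, False),
                ("p_d0", 1, 2, "m3", 0.0, 70.0, 0.3, 40.0, False)]
        stats = compute_reference_stats(make_cpp_table(rows), GEM)
        assert stats.r_mean.loc[0.0, "K"] == pytest.approx(100.0)
        assert stats.r_sd.loc[0.0, "K"] == pytest.approx(5.0)
        assert stats.y_max.loc[0.0, "L"] == pytest.approx(25.0)

    def test_too_few_refs_errors_naming_dose(self):
        rows = [("p_d0", 0, 0, "REF", 0.0, 100.0, 0.3, 10.0, False)]
        with pytest.raises(ValueError, match="dose\\(s\\) 0"):
            compute_reference_stats(make_cpp_table(rows), GEM)


class TestSubstitution:
    def test_no_growth_at_dose_replaced_by_ymax_for_L(self):
        stats = flat_ref_stats(ymax_l=40.0)
        prof = make_profile([10, 11, 12, 13, 99], no_growth=[False] * 4 + [True])
        out = substitute_ymax(prof, stats)
        assert out.y["L"][4] == 40.0
        assert out.y["K"][4] == 0.0 and out.y["r"][4] == 0.0

    def test_observed_L_above_ymax_capped(self):
        stats = flat_ref_stats(ymax_l=40.0)
        prof = make_profile([10, 55, 12, 13, 14])
        out = substitute_ymax(prof, stats)
        assert out.y["L"][1] == 40.0

    def test_all_observed_below_ymax_unchanged(self):
        stats = flat_ref_stats(ymax_l=40.0)
        prof = make_profile([10, 11, 12, 13, 14])
        out = substitute_ymax(prof, stats)
        np.testing.assert_array_equal(out.y["L"], prof.y["L"])
        np.testing.assert_array_equal(out.y["K"], prof.y["K"])

    def test_no_growth_at_d0_left_for_sentinel(self):
        stats = flat_ref_stats(ymax_l=40.0)
        prof = make_profile([99, 11, 12, 13, 14], no_growth=[True] + [False] * 4)
        out = substitute_ymax(prof, stats)
        assert out is prof  # unscorable, untouched


class TestScoreInteraction:
    def test_identity_mutant_equals_reference(self):
        stats = flat_ref_stats(r_l=10.0)
        prof = make_profile([10.0] * 5)
        res = score_interaction(prof, stats).set_index("cpp")
        assert res.loc["L", "shift"] == 0.0
        assert res.loc["L", "A"] == 0.0 and res.loc["L", "B"] == 0.0
        assert res.loc["L", "INT"] == 0.0

    def test_pure_shift_cancels(self):
        stats = flat_ref_stats(r_l=10.0)
        prof = make_profile([15.0] * 5)
        res = score_interaction(prof, stats).set_index("cpp")
        assert res.loc["L", "shift"] == pytest.approx(5.0)
        assert res.loc["L", "INT"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_profile_normal_equations(self):
        """Doses (0,5,10,20,30) with L_i = (0,1,2,4,6) solve to A = 0,
        B = 0.2, INT = 6.0 (hand-solved normal equations)."""
        stats = flat_ref_stats(r_l=0.0)
        prof = make_profile([0.0, 1.0, 2.0, 4.0, 6.0])
        res = score_interaction(prof, stats).set_index("cpp")
        assert res.loc["L", "A"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["L", "B"] == pytest.approx(0.2)
        assert res.loc["L", "INT"] == pytest.approx(6.0)

    def test_int_identity_holds_exactly(self):
        stats = flat_ref_stats(r_l=0.0)
        prof = make_profile([0.0, 2.0, 1.0, 5.0, 4.0])
        res = score_interaction(prof, stats).set_index("cpp")
        assert res.loc["L", "INT"] == res.loc["L", "A"] + res.loc["L", "B"] * 30.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        c=st.floats(min_value=-50, max_value=50),
        scale=st.floats(min_value=0.5, max_value=3.0),
    )
    def test_shift_invariance_and_slope_linearity(self, c, scale):
        """Adding a constant at every dose never changes INT; scaling the
        dose-linear component scales INT proportionally."""
        stats = flat_ref_stats(r_l=0.0)
        base = np.array([0.0, 1.0, 2.0, 4.0, 6.0])
        res0 = score_interaction(make_profile(base), stats).set_index("cpp")
        res_c = score_interaction(make_profile(base + c), stats).set_index("cpp")
        assert res_c.loc["L", "INT"] == pytest.approx(res0.loc["L", "INT"], abs=1e-9)
        res_s = score_interaction(make_profile(base * scale), stats).set_index("cpp")
        assert res_s.loc["L", "INT"] == pytest.approx(scale * res0.loc["L", "INT"], rel=1e-9)


class TestStandardize:
    def _results(self, ints, classes):
        rows = []
        for i, (v, cls) in enumerate(zip(ints, classes)):
            rows.append(dict(strain=f"s{i}", strain_class=cls, culture=f"a:0:{i}",
                             drug=GEM, cpp="L", shift=0.0, A=0.0, B=0.0, INT=v,
                             flagged=False, no_growth_at_d0=False))
        return pd.DataFrame(rows)

    def test_simple_arithmetic(self):
        """INT = 6.0 against reference mean 0, SD 1.5 gives z = 4.0."""
        refs = [-1.5, -0.5, 0.5, 1.5]  # mean 0, sample SD ~1.29; rescale below
        refs = list(np.array(refs) * (1.5 / np.std(refs, ddof=1)))
        res = self._results(refs + [6.0], ["reference"] * 4 + ["knockout"])
        out = standardize(res)
        assert out.loc[out["strain_class"] == "knockout", "z"].iloc[0] == pytest.approx(4.0)

    def test_int_at_stratum_mean_is_zero(self):
        res = self._results([1.0, 3.0, 2.0], ["reference", "reference", "knockout"])
        out = standardize(res)
        assert out.loc[out["strain_class"] == "knockout", "z"].iloc[0] == pytest.approx(0.0)

    def test_reference_self_standardization_exact(self):
        rng = np.random.default_rng(5)
        res = self._results(list(rng.normal(0, 2, 40)), ["reference"] * 40)
        out = standardize(res)
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_knockdown_stratum_standardized_separately(self):
        """KD strains use the KD-plate mean/SD, not the reference one."""
        refs = list(np.random.default_rng(0).normal(0, 1, 20))
        kds = list(np.random.default_rng(1).normal(10, 5, 20))
        res = self._results(refs + kds, ["reference"] * 20 + ["knockdown"] * 20)
        out = standardize(res)
        kd_z = out.loc[out["strain_class"] == "knockdown", "z"]
        assert kd_z.mean() == pytest.approx(0.0, abs=1e-9)
        assert kd_z.std(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "z_K,z_L,expected",
        [
            # printed profiles: PMR1 is an enhancer for both drugs,
            # CPR3 a suppressor for both
            (-3.8, 3.6, "enhancer"),    # PMR1 / gemcitabine
            (-9.8, 10.1, "enhancer"),   # PMR1 / cytarabine
            (2.1, -4.1, "suppressor"),  # CPR3 / gemcitabine
            (1.6, -2.8, "suppressor"),  # CPR3 / cytarabine
            (0.0, 0.0, "none"),
            (2.0, 2.0, "conflict"),     # K says suppressor, L says enhancer
            (np.nan, 2.5, "enhancer"),
            (np.nan, np.nan, "none"),
        ],
    )
    def test_rules(self, z_K, z_L, expected):
        assert classify(z_L, z_K) == expected

    def test_threshold_inclusive(self):
        assert classify(2.0, 0.0) == "enhancer"
        assert classify(-2.0, 0.0) == "suppressor"
        assert classify(1.999, -1.999, threshold=2.0) == "none"


class TestEndToEnd:
    def test_planted_enhancers_and_suppressors_called(self, scored, experiment):
        _, _, truth = experiment
        calls = (
            scored[(scored["cpp"] == "K") & (scored["strain_class"] == "knockout")]
            .set_index("strain")["class"]
        )
        for strain in ("YKO_0001", "YKO_0002", "YKO_0003"):
            assert calls[strain] == "enhancer"
        for strain in ("YKO_0004", "YKO_0005", "YKO_0006"):
            assert calls[strain] == "suppressor"

    def test_shift_only_strains_not_called(self, scored):
        calls = (
            scored[(scored["cpp"] == "K") & (scored["strain_class"] == "knockout")]
            .set_index("strain")["class"]
        )
        assert calls["YKO_0007"] == "none"
        assert calls["YKO_0008"] == "none"

    def test_reference_z_is_standard_normal_exactly(self, scored):
        refs = scored[(scored["strain_class"] == "reference") & ~scored["flagged"]]
        for cpp, grp in refs.groupby("cpp"):
            assert grp["z"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["z"].std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_sentinel_profile_flagged(self):
        """A strain with no growth even without drug is flagged, carries no
        z, and is never classified."""
        from conftest import small_config

        from phenomiq.simulate import generate_plate_experiment
        from phenomiq.growth import fit_cpp_table

        config = small_config(seed=33, n_mutant_strains=6, n_reference_cultures=16,
                              planted_effects={}, no_growth_fraction=0.0)
        ts, _ = generate_plate_experiment(config)
        # force one mutant's dose-0 culture to a blank
        mask = (ts["strain"] == "YKO_0001") & (ts["dose"] == 0.0)
        ts.loc[mask, "intensity"] = 1.0
        cpps = fit_cpp_table(ts)
        out = score_all(cpps, GEM)
        row = out[(out["strain"] == "YKO_0001") & (out["cpp"] == "L")].iloc[0]
        assert row["flagged"] and row["no_growth_at_d0"]
        assert np.isnan(row["z"]) and row["class"] == "none"
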