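"""Closed-form RNA kinetics, size factors, and the per-gene arm fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from polkin.slam import (
    SlamGeneData,
    fit_auxin,
    fit_control,
    model_curves,
    net_rate_ratio,
    size_factors_median_of_ratios,
)


def make_gene(sigma_ctrl=10.0, delta=0.5, sigma_aux=None, a0=None, reps=3, noise=None, rng=None):
    """Build a SlamGeneData from the model curves (optionally noised)."""
    sigma_aux = sigma_ctrl if sigma_aux is None else sigma_aux
    a0 = sigma_ctrl / delta if a0 is None else a0
    rows = []
    for arm, sig in (("ctrl", sigma_ctrl), ("aux", sigma_aux)):
        for t in (0.0, 1.0, 2.0, 4.0):
            fo, fn = model_curves(np.array([t]), sig, delta, a0=a0, arm=arm)
            total = fo[0] + fn[0]
            for rep in range(1, reps + 1):
                tot = total
                if noise and rng is not None:
                    tot = max(total * float(rng.normal(1, noise)), 1e-9)
                ntr = fn[0] / total if total > 0 else 0.0
                rows.append(("g", arm, t, rep, tot, ntr))
    return SlamGeneData("g", pd.DataFrame(rows, columns=["gene", "arm", "time_h", "rep", "count", "ntr"]))


class TestModelCurves:
    def test_time_zero_levels(self):
        fo, fn = model_curves(np.array([0.0]), 10.0, 0.5, arm="ctrl")
        assert fn[0] == 0.0 and fo[0] == pytest.approx(20.0)

    def test_control_total_is_steady_state_at_all_times(self):
        t = np.linspace(0, 6, 13)
        fo, fn = model_curves(t, 8.0, 0.4, arm="ctrl")
        assert np.allclose(fo + fn, 8.0 / 0.4)

    def test_long_time_limits(self):
        fo, fn = model_curves(np.array([200.0]), 10.0, 0.5, a0=77.0, arm="aux")
        assert fo[0] == pytest.approx(0.0, abs=1e-12)
        assert fn[0] == pytest.approx(20.0)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            model_curves(np.array([1.0]), 1.0, 0.0)

    def test_closed_form_matches_numeric_ode(self, rng):
        """a(t) = (a0 - sigma/delta) e^(-t delta) + sigma/delta vs solve_ivp."""
        for _ in range(20):
            sigma = float(rng.uniform(0.5, 50))
            delta = float(rng.uniform(0.05, 2.0))
            a0 = float(rng.uniform(0, 100))
            t = np.linspace(0, 4, 5)
            sol = solve_ivp(
                lambda _, a: sigma - delta * a, (0, 4), [a0], t_eval=t, rtol=1e-10, atol=1e-12
            )
            fo, fn = model_curves(t, sigma, delta, a0=a0, arm="aux")
            assert np.allclose(fo + fn, sol.y[0], rtol=1e-8)


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        df = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        assert np.allclose(size_factors_median_of_ratios(df), 1.0)

    def test_doubled_column_gets_factor_two(self):
        df = pd.DataFrame({"s1": [10.0, 20, 5], "s2": [20.0, 40, 10]})
        f = size_factors_median_of_ratios(df)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_global_scaling_invariance(self):
        """The reference is the per-gene geometric mean across samples, so a
        common scale factor cancels and the factors are unchanged."""
        df = pd.DataFrame({"s1": [10.0, 20, 5], "s2": [12.0, 30, 4]})
        f1 = size_factors_median_of_ratios(df)
        f7 = size_factors_median_of_ratios(df * 7)
        assert np.allclose(f7, f1)

    def test_scaling_one_column_scales_its_factor(self):
        df = pd.DataFrame({"s1": [10.0, 20, 5], "s2": [12.0, 30, 4], "s3": [9.0, 25, 6]})
        f1 = size_factors_median_of_ratios(df)
        df2 = df.assign(s1=df["s1"] * 3)
        f2 = size_factors_median_of_ratios(df2)
        assert f2["s1"] / f1["s1"] > 2.0  # grows (not exactly 3: the geomean moves too)

    def test_no_all_positive_gene_rejected(self):
        df = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError):
            size_factors_median_of_ratios(df)


class TestFits:
    def test_noiseless_control_recovery_to_four_digits(self):
        fit = fit_control(make_gene(sigma_ctrl=10.0, delta=0.5))
        assert fit.sigma == pytest.approx(10.0, rel=1e-4)
        assert fit.delta == pytest.approx(0.5, rel=1e-4)

    def test_noiseless_auxin_nonsteady_recovery(self):
        g = make_gene(sigma_ctrl=50.0, delta=0.5, sigma_aux=2.0, a0=100.0)
        fit = fit_auxin(g)
        assert fit.a0 == pytest.approx(100.0)
        assert fit.sigma == pytest.approx(2.0, rel=1e-4)
        assert fit.delta == pytest.approx(0.5, rel=1e-4)

    def test_a0_is_mean_of_time_zero_old_levels(self):
        g = make_gene(sigma_ctrl=10.0, delta=0.5, a0=100.0)
        tbl = g.table
        mask = (tbl["arm"] == "aux") & (tbl["time_h"] == 0)
        tbl.loc[mask, "count"] = [90.0, 100.0, 110.0]
        tbl.loc[mask, "ntr"] = 0.0
        fit = fit_auxin(SlamGeneData("g", tbl))
        assert fit.a0 == pytest.approx(100.0)

    def test_late_new_rna_points_excluded(self):
        fit = fit_control(make_gene())
        assert ("new", 2.0) in fit.excluded and ("new", 4.0) in fit.excluded
        fit_a = fit_auxin(make_gene())
        assert ("new", 2.0) in fit_a.excluded and ("new", 4.0) in fit_a.excluded

    def test_constant_old_rna_flags_delta_at_bound(self):
        g = make_gene(sigma_ctrl=10.0, delta=0.5)
        tbl = g.table.copy()
        tbl["ntr"] = 0.0
        tbl["count"] = 20.0  # no decay information at all
        fit = fit_control(SlamGeneData("g", tbl))
        assert fit.delta_at_bound and not fit.converged

    def test_single_timepoint_fails_loudly(self):
        g = make_gene()
        tbl = g.table[g.table["time_h"] == 0.0].reset_index(drop=True)
        with pytest.raises(ValueError):
            fit_control(SlamGeneData("g", tbl))

    def test_conservation_new_plus_old_equals_count(self):
        g = make_gene()
        lv = g.levels("ctrl")
        total = lv.groupby(["time_h", "rep"])["level"].sum().to_numpy()
        counts = g.table[g.table["arm"] == "ctrl"].sort_values(["time_h", "rep"])["count"].to_numpy()
        assert np.allclose(np.sort(total), np.sort(counts))

    def test_noisy_cohort_median_delta_error_under_ten_percent(self, rng):
        errs = []
        for _ in range(100):
            g = make_gene(sigma_ctrl=10.0, delta=0.5, noise=0.05, rng=rng)
            fit = fit_control(g)
            if fit.converged:
                errs.append(abs(fit.delta / 0.5 - 1.0))
        assert np.median(errs) < 0.10


class TestNetRateRatio:
    def test_equal_rates_give_unity(self):
        g = make_gene(sigma_ctrl=10.0, delta=0.5, sigma_aux=10.0)
        assert net_rate_ratio(fit_auxin(g), fit_control(g))[0] == pytest.approx(1.0, rel=1e-3)

    def test_eightfold_reduction(self):
        g = make_gene(sigma_ctrl=8.0, delta=0.5, sigma_aux=1.0)
        ratio, l2 = net_rate_ratio(fit_auxin(g), fit_control(g))
        assert ratio == pytest.approx(8.0, rel=1e-3)
        assert l2 == pytest.approx(3.0, abs=1e-3)
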