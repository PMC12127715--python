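import numpy as np
import pytest

from sgascreen.charts import percentile_to_z
from sgascreen.engine import (
    grid_axes,
    posterior_update,
    prior_density,
    screen_cohort,
    screen_record,
    sga_risk,
)
from sgascreen.fastscreen import target_column
from sgascreen.params import MaternalProfile

from conftest import sample_truncated_mixture

TARGETS = [(0.10, 37.0), (0.10, 32.0), (0.03, 37.0), (0.03, 32.0)]


def importance_rectangle(params, log10_moms, z_hi, g_hi, n, rng):
    """Importance-sampling oracle: prior draws weighted by the likelihood."""
    g, z = sample_truncated_mixture(params, (0.0, 0.0), n, rng)
    logw = np.zeros(n)
    for name, x in log10_moms.items():
        pl = params.likelihood_planes[name]
        logw += -0.5 * ((x - pl.mu(g, z)) / pl.sigma) ** 2
    w = np.exp(logw - logw.max())
    inside = ((z < z_hi) & (g < g_hi)).astype(float)
    est = np.sum(w * inside) / np.sum(w)
    se = np.sqrt(np.sum((w / np.sum(w)) ** 2 * (inside - est) ** 2))
    return est, se


class TestPriorDensity:
    def test_density_normalised_and_nonnegative(self, toy_params):
        grid = prior_density(None, toy_params)
        assert grid.integral() == pytest.approx(1.0, abs=1e-6)
        assert np.all(grid.density >= 0)

    def test_peak_at_baseline_means(self, toy_params):
        grid = prior_density(None, toy_params)
        g_mode, z_mode = grid.mode()
        assert g_mode == pytest.approx(39.5, abs=0.06)
        assert z_mode == pytest.approx(0.0, abs=0.03)

    def test_additive_shift_moves_peak_exactly(self, toy_params):
        base = prior_density(None, toy_params)
        shifted = prior_density((0.0, -0.5), toy_params)
        # the shifted density is a translation: peak moves by exactly the shift
        g0, z0 = base.mode()
        g1, z1 = shifted.mode()
        assert g1 == pytest.approx(g0, abs=1e-12)
        assert z1 == pytest.approx(z0 - 0.5, abs=0.021)

    def test_rectangle_mass_vs_monte_carlo(self, toy_params):
        grid = prior_density(None, toy_params, targets=TARGETS)
        rng = np.random.default_rng(11)
        n = 400_000
        g, z = sample_truncated_mixture(toy_params, (0.0, 0.0), n, rng)
        z10 = percentile_to_z(0.10)
        est = np.mean((z < z10) & (g < 37.0))
        se = np.sqrt(est * (1 - est) / n)
        assert grid.rect_prob(z10, 37.0) == pytest.approx(est, abs=3 * se)


class TestPosteriorUpdate:
    def test_empty_biomarker_set_is_identity(self, toy_params):
        prior = prior_density(None, toy_params)
        post = posterior_update(prior, {}, toy_params.likelihood_planes)
        assert np.max(np.abs(post.density - prior.density)) <= 1e-12

    def test_constant_likelihood_cancels(self, toy_params):
        # all log10 MoM = 0 with planes that are flat at 0 over the grid
        from sgascreen.params import LikelihoodPlane

        flat = {b: LikelihoodPlane(biomarker=b, knot_g=24.0, knot_z=-5.0,
                                   slope_g=0.0, slope_z=0.0, sigma=0.2)
                for b in toy_params.likelihood_planes}
        prior = prior_density(None, toy_params)
        post = posterior_update(prior, {b: 0.0 for b in flat}, flat)
        assert np.max(np.abs(post.density - prior.density)) <= 1e-10

    def test_rectangle_vs_importance_sampling(self, toy_params):
        rng = np.random.default_rng(29)
        moms = {"uta_pi": 0.15, "plgf": -0.2}
        prior = prior_density(None, toy_params, targets=TARGETS)
        post = posterior_update(prior, moms, toy_params.likelihood_planes)
        z10 = percentile_to_z(0.10)
        est, se = importance_rectangle(toy_params, moms, z10, 37.0, 400_000, rng)
        assert post.rect_prob(z10, 37.0) == pytest.approx(est, abs=3 * max(se, 1e-5))

    def test_extreme_moms_survive_in_log_space(self, toy_params):
        prior = prior_density(None, toy_params)
        post = posterior_update(prior, {"uta_pi": 3.0, "pappa": -3.0, "plgf": -3.0},
                                toy_params.likelihood_planes)
        assert post.integral() == pytest.approx(1.0, abs=1e-6)


class TestSgaRisk:
    def test_whole_support_is_one(self, toy_params):
        post = prior_density(None, toy_params)
        assert sga_risk(post, 0.999999, np.inf) == pytest.approx(1.0, abs=1e-5)

    def test_symmetric_prior_median_risk_half(self, toy_params):
        # centre the prior in the box so truncation keeps the z marginal symmetric
        from sgascreen.params import CompetingRisksParams, PriorComponent, PriorSpec

        params = CompetingRisksParams(
            prior=PriorSpec(components=[PriorComponent(
                weight=1.0, mean_g=33.5, mean_z=0.0, sd_g=2.0, sd_z=1.0, rho=0.4)]),
            mom_regressions=toy_params.mom_regressions,
            likelihood_planes=toy_params.likelihood_planes)
        post = prior_density(None, params)
        assert sga_risk(post, 0.5, np.inf) == pytest.approx(0.5, abs=1e-4)

    def test_monotone_in_percentile_and_cutoff(self, toy_params):
        prior = prior_density(None, toy_params, targets=TARGETS)
        post = posterior_update(prior, {"uta_pi": 0.1}, toy_params.likelihood_planes)
        risks_p = [sga_risk(post, p, 37.0) for p in (0.03, 0.10, 0.25, 0.5)]
        assert np.all(np.diff(risks_p) > 0)
        risks_g = [sga_risk(post, 0.10, gc) for gc in (30.0, 34.0, 37.0, 41.0)]
        assert np.all(np.diff(risks_g) > 0)
        assert sga_risk(post, 0.03, 37.0) <= sga_risk(post, 0.10, 37.0)

    def test_grid_refinement_converges(self, toy_params):
        moms = {"uta_pi": 0.1, "pappa": -0.15}
        coarse_axes = grid_axes(toy_params, TARGETS, g_step=0.05, z_step=0.02)
        fine_axes = grid_axes(toy_params, TARGETS, g_step=0.025, z_step=0.01)
        risks = []
        for g_axis, z_axis in (coarse_axes, fine_axes):
            prior = prior_density(None, toy_params, g_axis, z_axis)
            post = posterior_update(prior, moms, toy_params.likelihood_planes)
            risks.append(sga_risk(post, 0.10, 37.0))
        assert abs(risks[0] - risks[1]) < 1e-4


class TestScreenRecord:
    def test_deterministic_bit_for_bit(self, reference_profile, toy_params):
        raw = {"uta_pi": 1.9, "pappa": 2.2, "plgf": 28.0}
        a = screen_record(reference_profile, raw, toy_params, TARGETS)
        b = screen_record(reference_profile, raw, toy_params, TARGETS)
        assert a == b

    def test_no_biomarkers_equals_prior_risk(self, reference_profile, toy_params):
        got = screen_record(reference_profile, {}, toy_params, TARGETS)
        prior = prior_density(reference_profile, toy_params, targets=TARGETS)
        for (p, gc), risk in got.items():
            assert risk == pytest.approx(sga_risk(prior, p, gc), abs=1e-12)

    def test_nan_biomarkers_treated_as_missing(self, reference_profile, toy_params):
        got = screen_record(reference_profile,
                            {"uta_pi": float("nan"), "pappa": None}, toy_params, TARGETS)
        bare = screen_record(reference_profile, {}, toy_params, TARGETS)
        assert got == bare

    def test_rising_uta_pi_mom_never_lowers_risk(self, reference_profile, toy_params):
        reg = toy_params.mom_regressions["uta_pi"]
        from sgascreen.params import profile_features

        expected = 10.0 ** reg.expected_log10(profile_features(reference_profile))
        moms = np.linspace(0.5, 2.5, 50)
        risks = {t: [] for t in TARGETS}
        for m in moms:
            got = screen_record(reference_profile, {"uta_pi": m * expected},
                                toy_params, TARGETS)
            for t in TARGETS:
                risks[t].append(got[t])
        for t in TARGETS:
            assert np.all(np.diff(risks[t]) >= -1e-12)


class TestFastPathAgreesWithReference:
    def test_cohort_risks_match_per_record_engine(self, default_config):
        from sgascreen.cohort import simulate_cohort

        cfg = default_config
        df = simulate_cohort(40, 17, cfg)
        fast = screen_cohort(df, cfg.params, TARGETS)
        for i in range(len(df)):
            row = df.iloc[i]
            profile = MaternalProfile(
                age=row.age, weight=row.weight, height=row.height, race=row.race,
                smoker=bool(row.smoker), conception=row.conception,
                chronic_hypertension=bool(row.chronic_hypertension),
                diabetes=bool(row.diabetes), sle_aps=bool(row.sle_aps),
                parity=row.parity, prev_sga=bool(row.prev_sga),
                prev_pe=bool(row.prev_pe), prev_stillbirth=bool(row.prev_stillbirth),
                interpregnancy_interval=(None if row.parity == "nulliparous"
                                         else float(row.interpregnancy_interval)),
                ga_last_delivery=(None if row.parity == "nulliparous"
                                  else float(row.ga_last_delivery)),
                ga_at_screen=row.ga_at_screen)
            raw = {b: (None if np.isnan(row[b]) else float(row[b]))
                   for b in ("uta_pi", "pappa", "plgf")}
            ref = screen_record(profile, raw, cfg.params, TARGETS)
            for t in TARGETS:
                assert fast.iloc[i][target_column(*t)] == pytest.approx(ref[t], rel=1e-9)

    def test_forced_combo_sets_missing_to_nan(self, default_config):
        from sgascreen.cohort import simulate_cohort

        df = simulate_cohort(200, 19, default_config)
        out = screen_cohort(df, default_config.params, [(0.10, 37.0)],
                            biomarkers=("uta_pi", "plgf"))
        have = df["uta_pi"].notna() & df["plgf"].notna()
        col = out[target_column(0.10, 37.0)]
        assert col[have].notna().all()
        assert col[~have].isna().all()
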