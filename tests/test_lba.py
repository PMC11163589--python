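"""Oracles for the LBA densities, likelihood, sampler and ratio statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from loombias import lba, synthetic
from loombias.lba import (
    CUES,
    DRIFT_NAMES,
    MOTIONS,
    PARAM_NAMES,
    BehavioralDataset,
    GroupHyper,
    LBAParams,
    PosteriorChains,
    lba_cdf,
    lba_pdf,
)


def _params(A=0.5, b=1.2, t0=0.2, vc=2.5, ve=1.0):
    return LBAParams(
        A=A, b=b, t0=t0,
        v={n: (vc if n.endswith("_correct") else ve) for n in DRIFT_NAMES},
    )


class TestFirstPassage:
    def test_cdf_limit_is_finish_probability(self):
        # With a weak drift the accumulator may never finish:
        # lim F(t) = P(drift > 0).
        A, b, v = 0.5, 1.5, 0.4
        assert lba_cdf(1e7, A, b, v) == pytest.approx(stats.norm.cdf(v), abs=1e-4)
        assert lba_cdf(1e7, A, b, 3.0) == pytest.approx(stats.norm.cdf(3.0), abs=1e-4)

    def test_degenerate_race_concentrates_at_b_over_v(self):
        # A ~ 0 and s_v -> 0: deterministic first passage at b/v = 0.5.
        t = np.linspace(0.3, 0.7, 8001)
        dens = lba_pdf(t, 1e-9, 1.0, 2.0, s_v=1e-2)
        assert t[np.argmax(dens)] == pytest.approx(0.5, abs=1e-3)
        assert integrate.trapezoid(dens, t) == pytest.approx(1.0, abs=1e-2)

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            lba_pdf(np.array([-0.1]), 0.5, 1.0, 2.0)

    def test_pdf_is_derivative_of_cdf(self):
        t = np.linspace(0.05, 3.0, 3000)
        A, b, v = 0.7, 1.4, 1.8
        num = np.gradient(lba_cdf(t, A, b, v), t)
        assert np.allclose(num, lba_pdf(t, A, b, v), atol=5e-3)

    def test_density_matches_simulated_races(self, reference_params):
        """Analytic conditional CDF vs 1e5 Monte-Carlo races (KS oracle)."""
        p = reference_params
        sim = lba.simulate_lba(p, ("intensity", "looming"), 10**5, seed=3)
        rts = np.sort(sim[sim.response == "correct"].rt.to_numpy() - p.t0)
        grid = np.linspace(1e-4, 30, 30001)
        pdf = lba_pdf(grid, p.A, p.b, 2.5) * (1 - lba_cdf(grid, p.A, p.b, 1.0))
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0)
        ana = np.interp(rts, grid, cdf) / cdf[-1]
        emp = np.arange(1, rts.size + 1) / rts.size
        ks = np.max(np.abs(emp - ana))
        crit = stats.kstwobign.ppf(0.99) / np.sqrt(rts.size)
        assert ks < crit


class TestRaceLikelihood:
    def test_rt_at_or_below_t0_is_minus_inf(self):
        p = _params()
        trial = pd.Series({
            "cue": "intensity", "motion": "looming",
            "response": "correct", "rt": 0.19,
        })
        assert lba.race_likelihood(trial, p) == -np.inf

    def test_symmetric_drifts_give_equal_likelihood(self):
        p = _params(vc=1.7, ve=1.7)
        base = {"cue": "spectral", "motion": "receding", "rt": 0.8}
        lc = lba.race_likelihood(pd.Series({**base, "response": "correct"}), p)
        le = lba.race_likelihood(pd.Series({**base, "response": "incorrect"}), p)
        assert lc == pytest.approx(le)

    def test_defective_densities_integrate_to_finish_probability(self):
        """Quadrature over both responses vs Monte-Carlo finish frequency."""
        p = _params(A=0.6, b=1.3, vc=2.0, ve=0.8)
        grid = np.linspace(1e-4, 50, 50001)

        def defective(v_w, v_l):
            return lba_pdf(grid, p.A, p.b, v_w) * (
                1 - lba_cdf(grid, p.A, p.b, v_l)
            )

        total = integrate.trapezoid(defective(2.0, 0.8), grid) + integrate.trapezoid(
            defective(0.8, 2.0), grid
        )
        # Simulation conditions on finishing, so estimate the unconditional
        # finish probability directly from the race definition.
        rng = np.random.default_rng(0)
        drifts = rng.normal([2.0, 0.8], 1.0, size=(200000, 2))
        p_finish = np.mean((drifts > 0).any(axis=1))
        assert total == pytest.approx(p_finish, abs=3 * 0.5 / np.sqrt(200000) + 1e-3)


class TestSimulate:
    def test_dominant_drift_gives_high_accuracy(self):
        sim = lba.simulate_lba(_params(vc=8.0, ve=0.5), ("spectral", "looming"),
                               3000, seed=1)
        assert (sim.response == "correct").mean() > 0.99

    def test_accuracy_matches_numeric_integral(self):
        p = _params(A=0.6, b=1.3, vc=2.0, ve=0.8)
        sim = lba.simulate_lba(p, ("intensity", "receding"), 10**5, seed=9)
        acc = (sim.response == "correct").mean()
        grid = np.linspace(1e-4, 50, 50001)
        p_correct = integrate.trapezoid(
            lba_pdf(grid, p.A, p.b, 2.0) * (1 - lba_cdf(grid, p.A, p.b, 0.8)),
            grid,
        )
        drifts = np.random.default_rng(0).normal([2.0, 0.8], 1.0, (200000, 2))
        p_finish = np.mean((drifts > 0).any(axis=1))
        expected = p_correct / p_finish  # simulator conditions on finishing
        se = np.sqrt(expected * (1 - expected) / 10**5)
        assert acc == pytest.approx(expected, abs=3 * se + 1e-3)

    def test_seed_determinism(self):
        a = lba.simulate_lba(_params(), ("intensity", "looming"), 500, seed=4)
        b = lba.simulate_lba(_params(), ("intensity", "looming"), 500, seed=4)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("case", range(4))
    def test_ks_property_random_parameter_sets(self, case):
        """Simulator/density agreement across random valid parameter sets."""
        rng = np.random.default_rng(100 + case)
        A = rng.uniform(0.2, 1.0)
        b = A + rng.uniform(0.3, 1.2)
        vc = rng.uniform(1.5, 3.5)
        ve = rng.uniform(0.5, 1.2)
        p = _params(A=A, b=b, t0=0.15, vc=vc, ve=ve)
        sim = lba.simulate_lba(p, ("spectral", "receding"), 10**4, seed=case)
        rts = np.sort(sim[sim.response == "correct"].rt.to_numpy() - p.t0)
        grid = np.linspace(1e-4, 60, 60001)
        pdf = lba_pdf(grid, A, b, vc) * (1 - lba_cdf(grid, A, b, ve))
        cdf = integrate.cumulative_trapezoid(pdf, grid, initial=0)
        ana = np.interp(rts, grid, cdf) / cdf[-1]
        emp = np.arange(1, rts.size + 1) / rts.size
        ks = np.max(np.abs(emp - ana))
        assert ks < stats.kstwobign.ppf(0.99) / np.sqrt(rts.size)


def _tiny_dataset():
    rows = []
    rts = iter([0.61, 0.74, 0.55, 0.92, 0.66, 0.83, 0.58, 0.71])
    for pid in ("P0", "P1"):
        for cue in CUES:
            for motion in MOTIONS:
                rows.append({
                    "participant": pid, "cue": cue, "motion": motion,
                    "response": "correct" if len(rows) % 3 else "incorrect",
                    "rt": next(rts),
                })
    return BehavioralDataset(table=pd.DataFrame(rows))


class TestLogPosterior:
    def _hyper(self):
        return GroupHyper(
            mu={n: (0.5 if n == "A" else 1.5 if n == "b" else 0.25 if n == "t0"
                    else 2.5) for n in PARAM_NAMES},
            sigma={n: 0.5 for n in PARAM_NAMES},
        )

    def test_nonpositive_parameter_gives_minus_inf(self):
        data = _tiny_dataset()
        hyper = self._hyper()
        good = {pid: _params(t0=0.1) for pid in data.participants}
        assert np.isfinite(lba.log_posterior(data, good, hyper))
        bad = {pid: _params(t0=0.1) for pid in data.participants}
        bad["P0"] = LBAParams(
            A=0.5, b=1.2, t0=-0.1,
            v={n: 2.0 for n in DRIFT_NAMES},
        )
        assert lba.log_posterior(data, bad, hyper) == -np.inf

    def test_b_below_A_gives_minus_inf(self):
        data = _tiny_dataset()
        bad = {pid: LBAParams(A=1.5, b=1.2, t0=0.1,
                              v={n: 2.0 for n in DRIFT_NAMES})
               for pid in data.participants}
        assert lba.log_posterior(data, bad, self._hyper()) == -np.inf

    def test_empty_dataset_reduces_to_prior(self):
        empty = BehavioralDataset(table=pd.DataFrame(
            columns=["participant", "cue", "motion", "response", "rt"]
        ).astype({"rt": float}))
        hyper = self._hyper()
        params = {"P0": _params(t0=0.1)}
        got = lba.log_posterior(empty, params, hyper)
        # independent prior-only evaluation
        x = params["P0"].to_vector()
        expect = 0.0
        for i, name in enumerate(PARAM_NAMES):
            a = -hyper.mu[name] / hyper.sigma[name]
            expect += stats.truncnorm.logpdf(
                x[i], a, np.inf, loc=hyper.mu[name], scale=hyper.sigma[name]
            )
        expect += _hyperprior_oracle(hyper)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_matches_independent_term_by_term_summation(self):
        """Full joint density vs an independently coded evaluation."""
        data = _tiny_dataset()
        hyper = self._hyper()
        params = {pid: _params(A=0.4, b=1.1, t0=0.15, vc=2.2, ve=0.9)
                  for pid in data.participants}
        got = lba.log_posterior(data, params, hyper)

        expect = _hyperprior_oracle(hyper)
        for pid, p in params.items():
            x = p.to_vector()
            for i, name in enumerate(PARAM_NAMES):
                a = -hyper.mu[name] / hyper.sigma[name]
                expect += stats.truncnorm.logpdf(
                    x[i], a, np.inf, loc=hyper.mu[name],
                    scale=hyper.sigma[name],
                )
            for row in data.for_participant(pid).itertuples(index=False):
                w = f"v_{row.cue}_{row.motion}_" + (
                    "correct" if row.response == "correct" else "incorrect"
                )
                l = f"v_{row.cue}_{row.motion}_" + (
                    "incorrect" if row.response == "correct" else "correct"
                )
                td = row.rt - p.t0
                f = lba_pdf(np.array([td]), p.A, p.b, p.v[w])[0]
                s = 1 - lba_cdf(np.array([td]), p.A, p.b, p.v[l])[0]
                expect += np.log(f) + np.log(s)
        assert got == pytest.approx(expect, rel=1e-9)


def _hyperprior_oracle(hyper: GroupHyper) -> float:
    total = 0.0
    for name in PARAM_NAMES:
        m0, s0 = lba._location_prior(name)
        total += stats.truncnorm.logpdf(
            hyper.mu[name], -m0 / s0, np.inf, loc=m0, scale=s0
        )
        shape, scale = lba._scale_prior(name)
        total += stats.gamma.logpdf(hyper.sigma[name], a=shape, scale=scale)
    return float(total)


class TestGelmanRubin:
    def test_hand_computed_two_chain_example(self):
        # chains: [1, 2, 3, 4] and [3, 4, 5, 6]
        x = np.array([[1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]])
        m, n = 2, 4
        W = (np.var(x[0], ddof=1) + np.var(x[1], ddof=1)) / 2  # 5/3
        B = n * np.var([x[0].mean(), x[1].mean()], ddof=1)  # 4*2 = 8
        expect = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert lba.gelman_rubin(x) == pytest.approx(expect, rel=1e-12)

    def test_degenerate_chains_flagged_not_crashed(self):
        x = np.ones((3, 10))
        assert np.isnan(lba.gelman_rubin(x))

    def test_iid_chains_approach_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 4000))
        assert lba.gelman_rubin(x) == pytest.approx(1.0, abs=0.01)


class TestDeMcmc:
    def test_seed_determinism(self):
        truth = synthetic.BehaviorTruth(
            n_participants=2, trials_per_condition=10, seed=3
        )
        data, _ = synthetic.gen_behavior(truth)
        a = lba.de_mcmc_fit(data, n_chains=4, n_iter=30, n_burn=10, thin=2, seed=5)
        b = lba.de_mcmc_fit(data, n_chains=4, n_iter=30, n_burn=10, thin=2, seed=5)
        assert np.array_equal(a.group_samples, b.group_samples)
        assert np.array_equal(a.participant_samples, b.participant_samples)

    def test_retained_draw_count_contract(self):
        truth = synthetic.BehaviorTruth(
            n_participants=2, trials_per_condition=10, seed=3
        )
        data, _ = synthetic.gen_behavior(truth)
        fit = lba.de_mcmc_fit(data, n_chains=4, n_iter=40, n_burn=20, thin=5, seed=5)
        assert fit.n_draws == 4  # (40 - 20) / 5
        assert fit.group_samples.shape == (4, 4, 22)

    def test_too_few_chains_rejected(self):
        truth = synthetic.BehaviorTruth(
            n_participants=2, trials_per_condition=10, seed=3
        )
        data, _ = synthetic.gen_behavior(truth)
        with pytest.raises(ValueError):
            lba.de_mcmc_fit(data, n_chains=3, n_iter=10, n_burn=5, thin=1, seed=5)

    def test_missing_condition_rejected(self):
        truth = synthetic.BehaviorTruth(
            n_participants=2, trials_per_condition=10, seed=3
        )
        data, _ = synthetic.gen_behavior(truth)
        pid = data.participants[0]
        table = data.table[
            ~((data.table.participant == pid)
              & (data.table.cue == "spectral")
              & (data.table.motion == "looming"))
        ].reset_index(drop=True)
        with pytest.raises(ValueError):
            lba.de_mcmc_fit(BehavioralDataset(table=table), n_chains=4,
                            n_iter=10, n_burn=5, thin=1, seed=5)

    def test_recovery_and_convergence_on_fixture(self, tiny_fit):
        """Group locations recovered within 3 posterior SD; chains converge."""
        truth, data, chains = tiny_fit
        flat = chains.flat_group()
        for i, name in enumerate(PARAM_NAMES):
            z = abs(flat[:, i].mean() - truth.hyper.mu[name]) / flat[:, i].std()
            assert z < 3.0, name
        rhat = lba.gelman_rubin_report(chains)["rhat"].to_numpy()
        assert np.nanmax(rhat) < 1.05

    def test_chains_round_trip(self, tmp_path, tiny_fit):
        _, _, chains = tiny_fit
        chains.save(tmp_path / "chains.npz")
        back = PosteriorChains.load(tmp_path / "chains.npz")
        assert np.array_equal(back.group_samples, chains.group_samples)
        assert back.participants == chains.participants


def _constant_chains(mu_by_name, sigma_by_name, n_chains=4, n_draws=10,
                     participants=("P0",)):
    k = len(PARAM_NAMES)
    group = np.empty((n_chains, n_draws, 2 * k))
    for i, n in enumerate(PARAM_NAMES):
        group[:, :, i] = mu_by_name[n]
        group[:, :, k + i] = sigma_by_name[n]
    part = np.empty((n_chains, n_draws, len(participants), k))
    for i, n in enumerate(PARAM_NAMES):
        part[:, :, :, i] = mu_by_name[n]
    return PosteriorChains(
        participant_samples=part, group_samples=group,
        participants=list(participants), config={},
    )


class TestLoomingRatio:
    def test_identical_posteriors_give_half(self):
        mu = {n: 2.0 for n in PARAM_NAMES}
        mu.update({"A": 0.5, "b": 1.5, "t0": 0.2})
        chains = _constant_chains(mu, {n: 0.4 for n in PARAM_NAMES})
        res = lba.looming_ratio(chains, n_samples=4000, n_reps=400, seed=0)
        assert res.point == pytest.approx(0.5, abs=0.01)
        assert 0.3 < res.p_gt_chance < 0.7

    def test_large_separation_drives_r_to_one(self):
        mu = {n: 1.0 for n in PARAM_NAMES}
        for cue in CUES:
            mu[f"v_{cue}_looming_correct"] = 8.0
            mu[f"v_{cue}_receding_correct"] = 1.0
        chains = _constant_chains(mu, {n: 0.3 for n in PARAM_NAMES})
        res = lba.looming_ratio(chains, n_samples=2000, n_reps=200, seed=0)
        assert res.point > 0.99
        assert res.p_gt_chance == 1.0

    @pytest.mark.parametrize(
        "mu_l,s_l,mu_r,s_r",
        [(3.0, 0.5, 2.5, 0.5), (2.0, 1.0, 2.0, 0.3), (3.5, 0.4, 2.0, 0.8),
         (1.0, 0.2, 1.4, 0.6)],
    )
    def test_closed_form_oracle_grid(self, mu_l, s_l, mu_r, s_r):
        """Mean r equals Phi((mu_L-mu_R)/sqrt(s_L^2+s_R^2)) for fixed hypers."""
        mu = {n: 1.0 for n in PARAM_NAMES}
        sd = {n: 0.3 for n in PARAM_NAMES}
        for cue in CUES:
            mu[f"v_{cue}_looming_correct"] = mu_l
            sd[f"v_{cue}_looming_correct"] = s_l
            mu[f"v_{cue}_receding_correct"] = mu_r
            sd[f"v_{cue}_receding_correct"] = s_r
        chains = _constant_chains(mu, sd)
        res = lba.looming_ratio(chains, n_samples=5000, n_reps=200, seed=1)
        expect = lba.ratio_closed_form(mu_l, s_l, mu_r, s_r)
        assert res.point == pytest.approx(expect, abs=0.01)

    def test_per_cue_mode(self):
        mu = {n: 1.0 for n in PARAM_NAMES}
        mu["v_intensity_looming_correct"] = 3.0
        mu["v_intensity_receding_correct"] = 1.0
        chains = _constant_chains(mu, {n: 0.5 for n in PARAM_NAMES})
        res_i = lba.looming_ratio(chains, n_samples=2000, n_reps=100,
                                  cue="intensity", seed=0)
        res_s = lba.looming_ratio(chains, n_samples=2000, n_reps=100,
                                  cue="spectral", seed=0)
        assert res_i.point > 0.95
        assert res_s.point == pytest.approx(0.5, abs=0.03)


class TestPosteriorPredictive:
    def test_draw_count_contract(self, tiny_fit):
        _, data, chains = tiny_fit
        rep = lba.posterior_predictive_check(
            chains, data, draws_per_chain=3, seed=0
        )
        assert (rep["n_draws"] == 3 * chains.n_chains).all()
        assert set(rep["statistic"]) == {"rt_quartile_coverage", "accuracy_diff"}
        assert len(rep) == 8  # 4 conditions x 2 statistics

    def test_well_fit_model_centers_near_reference(self, tiny_fit):
        _, data, chains = tiny_fit
        rep = lba.posterior_predictive_check(
            chains, data, draws_per_chain=5, seed=0
        )
        rt = rep[rep.statistic == "rt_quartile_coverage"]
        assert ((rt.ci_lo <= 0.5) & (rt.ci_hi >= 0.5)).mean() >= 0.75

    def test_misspecified_posterior_excludes_reference(self, tiny_fit):
        _, data, _ = tiny_fit
        # Posterior concentrated far from the generating truth: enormous
        # drift -> simulated RTs pile up far below the observed quartiles.
        mu = {n: 0.3 for n in PARAM_NAMES}
        mu.update({"A": 0.2, "b": 0.4, "t0": 0.01})
        for n in DRIFT_NAMES:
            mu[n] = 12.0
        chains = _constant_chains(
            mu, {n: 0.01 for n in PARAM_NAMES},
            participants=sorted(data.participants),
        )
        rep = lba.posterior_predictive_check(
            chains, data, draws_per_chain=3, seed=0
        )
        rt = rep[rep.statistic == "rt_quartile_coverage"]
        assert (rt.ci_hi < 0.5).all()


class TestBehaviorSummary:
    def test_catch_error_exclusion(self):
        rows = []
        for pid, err in (("good", 0.1), ("bad", 0.3)):
            for i in range(20):
                rows.append({
                    "participant": pid, "cue": "intensity",
                    "motion": "static_near_onset",
                    "response": "incorrect" if i < err * 20 else "correct",
                    "rt": 0.9,
                })
                rows.append({
                    "participant": pid, "cue": "intensity", "motion": "looming",
                    "response": "correct", "rt": 1.0,
                })
        rep = lba.behavior_summary(pd.DataFrame(rows))
        assert rep["excluded_participants"] == ["bad"]

    def test_all_correct_quartiles(self):
        rows = [
            {"participant": f"P{i}", "cue": "spectral",
             "motion": m, "response": "correct", "rt": 0.8 + 0.01 * i}
            for i in range(4)
            for m in ("static_near_onset", "looming")
        ]
        rep = lba.behavior_summary(pd.DataFrame(rows))
        assert rep["static_hit_rate_quartiles"] == [1.0, 1.0, 1.0]

    def test_no_static_trials_not_applicable(self):
        rows = [{"participant": "P0", "cue": "spectral", "motion": "looming",
                 "response": "correct", "rt": 0.8}]
        assert lba.behavior_summary(pd.DataFrame(rows)) == {"applicable": False}

    def test_signed_rank_matches_exhaustive_enumeration(self):
        """Wilcoxon V and p vs brute-force sign-pattern enumeration, N=5."""
        static = np.array([0.95, 0.99, 0.92, 0.97, 0.90])
        motion = np.array([0.60, 0.72, 0.55, 0.81, 0.66])
        d = static - motion
        ranks = stats.rankdata(np.abs(d))
        v_obs = ranks[d > 0].sum()
        # enumerate all 2^5 sign assignments for the exact null distribution
        vs = [
            np.sum(ranks[np.array(signs, dtype=bool)])
            for signs in itertools.product((0, 1), repeat=5)
        ]
        vs = np.array(vs)
        p_exact = 2 * min(
            np.mean(vs <= v_obs), np.mean(vs >= v_obs)
        )
        res = stats.wilcoxon(static, motion)
        assert res.statistic == pytest.approx(min(v_obs, ranks.sum() - v_obs))
        assert res.pvalue == pytest.approx(min(p_exact, 1.0), abs=1e-9)


def test_dataset_tsv_round_trip(tmp_path):
    truth = synthetic.BehaviorTruth(n_participants=2, trials_per_condition=4, seed=1)
    data, _ = synthetic.gen_behavior(truth)
    data.to_tsv(tmp_path / "d.tsv")
    back = BehavioralDataset.from_tsv(tmp_path / "d.tsv")
    pd.testing.assert_frame_equal(
        back.table[["participant", "cue", "motion", "response", "rt"]],
        data.table[["participant", "cue", "motion", "response", "rt"]],
    )
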