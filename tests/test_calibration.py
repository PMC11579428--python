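"""Prior sampling, viability filtering, likelihood, and MCMC selection."""
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hydrostand.calibration import (ObservationSet, PriorRange, PriorSpec,
                                    log_likelihood, mahalanobis,
                                    sample_priors, select_assemblages,
                                    viability_filter)
from hydrostand.traits import TRAIT_FIELDS, TraitEnsemble


def obs_from_output(output, sigma=None, override=None):
    """ObservationSet equal to an output's monthly aggregates (plus edits)."""
    sigma = sigma or {"et": 0.2, "gpp": 0.2, "swc": 0.1, "runoff": 0.3}
    monthly = output.monthly_observables()
    rows = []
    for var in ("et", "gpp", "swc", "runoff"):
        for month, value in monthly[var].items():
            v = value
            if override and (str(month), var) in override:
                v = override[(str(month), var)]
            rows.append({"month": str(month), "variable": var,
                         "value": v, "sigma_log": sigma[var]})
    return ObservationSet(pd.DataFrame(rows))


class TestPriors:
    def test_latin_hypercube_size_bounds_and_strata(self):
        spec = PriorSpec()
        n = 1000
        ens = TraitEnsemble.from_assemblages(sample_priors(spec, n, seed=0))
        assert len(ens) == n
        for name in TRAIT_FIELDS:
            col = ens.column(name)
            r = spec.ranges[name]
            assert col.min() >= r.lower and col.max() <= r.upper
            # one sample per equal-probability stratum
            if r.dist == "log-uniform":
                u = (np.log(col) - math.log(r.lower)) \
                    / (math.log(r.upper) - math.log(r.lower))
            else:
                u = (col - r.lower) / (r.upper - r.lower)
            counts = np.bincount(np.minimum((u * n).astype(int), n - 1),
                                 minlength=n)
            assert np.all(counts == 1)

    def test_reproducible_under_seed(self):
        a = sample_priors(PriorSpec(), 50, seed=7)
        b = sample_priors(PriorSpec(), 50, seed=7)
        assert all(x == y for x, y in zip(a, b))

    def test_yaml_round_trip(self, tmp_path):
        spec = PriorSpec()
        spec.to_yaml(tmp_path / "priors.yaml")
        back = PriorSpec.from_yaml(tmp_path / "priors.yaml")
        assert back.ranges == spec.ranges

    def test_invalid_spec_names_the_trait(self):
        ranges = dict(PriorSpec().ranges)
        ranges["g1"] = PriorRange(12.0, 4.0)
        with pytest.raises(ValueError, match="g1"):
            PriorSpec(ranges)
        del ranges["g1"]
        with pytest.raises(ValueError, match="g1"):
            PriorSpec(ranges)


class TestViability:
    def test_no_growth_dropped(self, output_factory):
        out = output_factory(days=365, gpp=150.0 / 365.0, plc_stem=0.1)
        retained, reasons = viability_filter({0: out})
        assert retained == [] and "no-growth" in reasons[0]

    def test_lethal_plc_dropped(self, output_factory):
        out = output_factory(days=365, gpp=900.0 / 365.0, plc_stem=0.85)
        retained, reasons = viability_filter({0: out})
        assert retained == [] and "lethal" in reasons[0]

    def test_healthy_member_retained(self, output_factory):
        out = output_factory(days=365, gpp=250.0 / 365.0, plc_stem=0.4)
        retained, reasons = viability_filter({0: out})
        assert retained == [0] and reasons == {}


class TestMahalanobis:
    def test_zero_at_center(self):
        assert mahalanobis([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_identity_covariance_is_euclidean(self):
        assert mahalanobis([3.0, 4.0], [0.0, 0.0], np.eye(2)) \
            == pytest.approx(5.0)

    def test_diagonal_covariance_example(self):
        d = mahalanobis([1.0, 2.0], [0.0, 0.0], np.diag([1.0, 4.0]))
        assert d == pytest.approx(math.sqrt(2.0))

    def test_singular_covariance_suggests_ridge(self):
        with pytest.raises(ValueError, match="ridge"):
            mahalanobis([1.0, 2.0], [0.0, 0.0], np.ones((2, 2)))
        # a jitter restores positive-definiteness
        assert mahalanobis([1.0, 2.0], [0.0, 0.0], np.ones((2, 2)),
                           jitter=1e-6) > 0


class TestLogLikelihood:
    def test_maximum_at_exact_match(self, output_factory):
        out = output_factory(days=90)
        obs = obs_from_output(out)
        best = log_likelihood(out, obs)
        worse = output_factory(days=90, gpp=8.0 * 1.15)
        assert log_likelihood(worse, obs) < best

    def test_one_term_gaussian_arithmetic(self, output_factory):
        # single month; gpp simulated at obs * e^0.5 with sigma_log = 0.5
        out = output_factory(days=31, gpp=100.0 * math.exp(0.5) / 31.0)
        sim_monthly = out.monthly_observables()
        sigma = {"et": 0.2, "gpp": 0.5, "swc": 0.1, "runoff": 0.3}
        obs = obs_from_output(out, sigma=sigma,
                              override={("2003-01", "gpp"): 100.0})
        expected = sum(-math.log(sigma[v] * math.sqrt(2 * math.pi))
                       for v in ("et", "swc", "runoff"))
        expected += -math.log(0.5 * math.sqrt(2 * math.pi)) - 0.5
        assert log_likelihood(out, obs) == pytest.approx(expected, abs=1e-9)

    def test_matches_independent_density_oracle(self, output_factory):
        rng = np.random.default_rng(4)
        out = output_factory(days=120, gpp=rng.uniform(5, 12),
                             transpiration=rng.uniform(0.5, 2.0))
        for sig_scale in (1.0, 2.0):
            sigma = {"et": 0.2 * sig_scale, "gpp": 0.2 * sig_scale,
                     "swc": 0.1 * sig_scale, "runoff": 0.3 * sig_scale}
            obs = obs_from_output(out, sigma=sigma)
            obs_df = obs.df.copy()
            obs_df["value"] = obs_df["value"] * rng.uniform(0.8, 1.2,
                                                            size=len(obs_df))
            obs_perturbed = ObservationSet(obs_df)
            # brute-force: scipy normal density term by term
            sim = out.monthly_observables()
            sim.index = sim.index.astype(str)
            expected = 0.0
            for _, row in obs_perturbed.df.iterrows():
                expected += scipy.stats.norm.logpdf(
                    math.log(sim.loc[row["month"], row["variable"]]),
                    loc=math.log(row["value"]), scale=row["sigma_log"])
            assert log_likelihood(out, obs_perturbed) \
                == pytest.approx(expected, rel=1e-12)

    def test_misaligned_months_rejected(self, output_factory):
        out = output_factory(days=60)
        obs = obs_from_output(output_factory(days=60, start="2010-01-01"))
        with pytest.raises(ValueError, match="months"):
            log_likelihood(out, obs)


def _toy_selection_problem(output_factory, n=6):
    """Ensemble whose outputs differ only in a GPP level; member n//2 fits."""
    members = sample_priors(PriorSpec(), n, seed=3)
    ensemble = TraitEnsemble.from_assemblages(members)
    levels = np.linspace(5.0, 11.0, n)
    outputs = {i: output_factory(days=90, gpp=levels[i]) for i in range(n)}
    obs = obs_from_output(outputs[n // 2])
    return ensemble, outputs, obs


class TestSelection:
    def test_chain_bookkeeping_and_metropolis_rule(self, output_factory):
        ensemble, outputs, obs = _toy_selection_problem(output_factory)
        res = select_assemblages(ensemble, outputs, obs, PriorSpec(),
                                 steps=400, burn_in=100, seed=1)
        assert len(res.trace) == 400
        assert len(res.trace.iloc[100:]) == 400 - 100
        ll = {i: log_likelihood(outputs[i], obs) for i in ensemble.ids}
        cur = res.trace["current_id"].shift(1)
        for _, row in res.trace.iloc[1:].iterrows():
            if ll[row["proposed_id"]] > ll[int(cur[row.name])]:
                assert row["accepted"]  # uphill moves always accepted

    def test_selected_ids_and_intervals_inside_priors(self, output_factory):
        ensemble, outputs, obs = _toy_selection_problem(output_factory)
        spec = PriorSpec()
        res = select_assemblages(ensemble, outputs, obs, spec,
                                 steps=400, burn_in=100, seed=1)
        assert set(res.selected_ids) <= set(ensemble.ids)
        for name in TRAIT_FIELDS:
            lo, hi = res.interval(name)
            r = spec.ranges[name]
            assert r.lower - 1e-12 <= lo <= hi <= r.upper + 1e-12

    def test_order_invariance(self, output_factory):
        ensemble, outputs, obs = _toy_selection_problem(output_factory)
        permuted = TraitEnsemble(ensemble.values[::-1].copy(),
                                 ids=list(ensemble.ids)[::-1])
        a = select_assemblages(ensemble, outputs, obs, PriorSpec(),
                               steps=300, burn_in=50, seed=9)
        b = select_assemblages(permuted, outputs, obs, PriorSpec(),
                               steps=300, burn_in=50, seed=9)
        assert a.selected_ids == b.selected_ids

    def test_sigma_limits(self, output_factory):
        ensemble, outputs, _ = _toy_selection_problem(output_factory)
        target = outputs[3]
        # near-zero error: selection concentrates on the best-fitting member
        tight = obs_from_output(target, sigma={"et": 1e-3, "gpp": 1e-3,
                                               "swc": 1e-3, "runoff": 1e-3})
        res_tight = select_assemblages(ensemble, outputs, tight, PriorSpec(),
                                       steps=500, burn_in=100, seed=2)
        assert res_tight.selected_ids == [3]
        # huge error: no constraint, selection is prior-like (95% of members)
        loose = obs_from_output(target, sigma={"et": 50.0, "gpp": 50.0,
                                               "swc": 50.0, "runoff": 50.0})
        res_loose = select_assemblages(ensemble, outputs, loose, PriorSpec(),
                                       steps=2000, burn_in=100, seed=2)
        assert len(res_loose.selected_ids) == math.ceil(0.95 * len(ensemble))

    def test_ranking_cross_check_keeps_top_95_percent(self, output_factory):
        ensemble, outputs, obs = _toy_selection_problem(output_factory)
        res = select_assemblages(ensemble, outputs, obs, PriorSpec(),
                                 steps=200, burn_in=50, seed=0,
                                 method="ranking")
        assert len(res.selected_ids) == math.ceil(0.95 * len(ensemble))
        ll = {i: log_likelihood(outputs[i], obs) for i in ensemble.ids}
        dropped = set(ensemble.ids) - set(res.selected_ids)
        assert all(ll[d] <= min(ll[k] for k in res.selected_ids)
                   for d in dropped)

    def test_degenerate_inputs_rejected(self, output_factory):
        ensemble, outputs, obs = _toy_selection_problem(output_factory)
        with pytest.raises(ValueError, match="empty"):
            select_assemblages(TraitEnsemble(np.empty((0, len(TRAIT_FIELDS)))),
                               outputs, obs, PriorSpec(), steps=30, burn_in=20)
        with pytest.raises(ValueError, match="steps"):
            select_assemblages(ensemble, outputs, obs, PriorSpec(),
                               steps=10, burn_in=20)
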