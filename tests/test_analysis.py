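"""Spectra, Pareto fronts, Monod scans, envelope sensitivities, knockouts."""

import math

import numpy as np
import pytest

from efcm.analysis import (
    EcmCache,
    RateYieldPoint,
    epistasis,
    growth_sensitivities,
    knockout_analysis,
    monod_scan,
    pareto_front,
    rate_yield_spectrum,
)
from efcm.ecm import Condition, minimize_enzyme_cost
from efcm.efm import enumerate_efms
from efcm.growth import growth_rate_from_cost
from efcm.synth import make_branch_tradeoff_model, make_chain_model, make_diamond_model

from .oracles import pareto_by_domination


@pytest.fixture(scope="module")
def branch_spectrum(branch_model, branch_efms, shared_cache):
    points, failures = rate_yield_spectrum(
        branch_efms, branch_model, Condition(), cache=shared_cache
    )
    assert not failures
    return points


class TestSpectrum:
    def test_branch_toy_shows_strict_tradeoff(self, branch_spectrum):
        assert len(branch_spectrum) == 2
        by_yield = sorted(branch_spectrum, key=lambda p: p.yield_g_per_cmol)
        low, high = by_yield
        assert low.yield_g_per_cmol == pytest.approx(10.0)
        assert high.yield_g_per_cmol == pytest.approx(20.0)
        assert low.mu > high.mu  # cheap low-yield route grows faster

    def test_single_efm_spectrum_equals_direct_solve(self, chain_model, chain_efms):
        points, _ = rate_yield_spectrum(chain_efms, chain_model, Condition())
        assert len(points) == 1
        sol = minimize_enzyme_cost(chain_efms.efms[0], chain_model, Condition())
        mu = growth_rate_from_cost(sol.e_met, chain_model.growth_params)
        assert points[0].mu == pytest.approx(mu, rel=1e-9)


class TestPareto:
    def test_single_point_is_its_own_front(self):
        p = RateYieldPoint(0, 10.0, 0.5, 100.0)
        assert pareto_front([p]) == [p]

    def test_matches_domination_oracle_on_random_points(self):
        rng = np.random.default_rng(2024)
        points = [
            RateYieldPoint(i, float(rng.uniform(1, 25)), float(rng.uniform(0.05, 1.3)),
                           0.0)
            for i in range(100)
        ]
        front = pareto_front(points)
        assert {p.efm_id for p in front} == pareto_by_domination(points)
        # ordering contract: descending yield
        yields = [p.yield_g_per_cmol for p in front]
        assert yields == sorted(yields, reverse=True)

    def test_front_members_mutually_nondominated_and_cover(self):
        rng = np.random.default_rng(77)
        points = [
            RateYieldPoint(i, float(rng.uniform(1, 25)), float(rng.uniform(0.05, 1.3)),
                           0.0)
            for i in range(60)
        ]
        front = pareto_front(points)
        ids = {p.efm_id for p in front}

        def dominates(p, q):
            return (p.mu >= q.mu and p.yield_g_per_cmol >= q.yield_g_per_cmol
                    and (p.mu > q.mu or p.yield_g_per_cmol > q.yield_g_per_cmol))

        for p in front:
            assert not any(dominates(q, p) for q in front)
        for p in points:
            if p.efm_id not in ids:
                assert any(dominates(q, p) for q in front)

    def test_branch_front_contains_both_efms(self, branch_spectrum):
        assert len(pareto_front(branch_spectrum)) == 2


def _oxygen_toy():
    """Branch trade-off variant: the fast route is oxygen-dependent, the slow
    one oxygen-sensitive, and oxygen boosts the fast route's saturation."""
    model = make_branch_tradeoff_model(seed=0)
    from fractions import Fraction

    from efcm.model import Metabolite

    model.metabolites.append(
        Metabolite("o2_ext", is_external=True, fixed_conc=0.21, carbon_count=0)
    )
    fast = model.reaction("low_yield")
    fast.stoich["o2_ext"] = Fraction(-1)
    fast.kinetics.km["o2_ext"] = 0.1
    fast.kinetics.keq *= 1e4  # keep the route strongly driven despite O2 term
    fast.tags = frozenset({"oxygen_dependent"})
    model.reaction("high_yield").tags = frozenset({"oxygen_sensitive"})
    model.oxygen_metabolite_id = "o2_ext"
    return model


class TestMonod:
    def test_grid_cells_equal_independent_single_runs(self, branch_model, branch_efms):
        glc = [1.0, 10.0, 100.0]
        surface = monod_scan(branch_model, branch_efms, glc, [0.21])
        for i, g in enumerate(glc):
            cond = Condition(external_conc={"glc_ext": g})
            points, _ = rate_yield_spectrum(branch_efms, branch_model, cond)
            assert surface.mu[i, 0] == pytest.approx(max(p.mu for p in points),
                                                     rel=1e-9)

    def test_mu_nondecreasing_in_glucose(self, branch_model, branch_efms):
        glc = np.geomspace(1e-4, 100.0, 6)
        surface = monod_scan(branch_model, branch_efms, glc, [0.21])
        mus = surface.mu[:, 0]
        assert all(a <= b + 1e-12 for a, b in zip(mus, mus[1:]))

    def test_anaerobic_efm_mu_flat_in_oxygen(self):
        model = _oxygen_toy()
        efms = enumerate_efms(model)
        o2_grid = [1e-4, 1e-3, 0.21, 10.0]
        anaerobic = [e for e in efms.biomass_producing(model)
                     if not e.uses_tag("oxygen_dependent", model)]
        assert anaerobic
        efm = anaerobic[0]
        mus = []
        for o2 in o2_grid:
            sol = minimize_enzyme_cost(
                efm, model, Condition(external_conc={"o2_ext": o2})
            )
            mus.append(growth_rate_from_cost(sol.e_met, model.growth_params))
        assert max(mus) - min(mus) <= 1e-9 * max(mus)

    def test_zero_oxygen_applies_anaerobic_rule(self):
        model = _oxygen_toy()
        efms = enumerate_efms(model)
        surface = monod_scan(model, efms, [100.0], [0.0, 0.21])
        winner_anoxic = surface.winner[0, 0]
        winner_oxic = surface.winner[0, 1]
        assert not efms[winner_anoxic].uses_tag("oxygen_dependent", model)
        assert not efms[winner_oxic].uses_tag("oxygen_sensitive", model)

    def test_infeasible_cells_flagged_not_dropped(self, chain_model, chain_efms):
        # knock the only EFM out via an absurdly low glucose level that empties
        # the polytope (driving force of uptake cannot stay positive)
        surface = monod_scan(chain_model, chain_efms, [1e-12], [0.21])
        assert surface.winner[0, 0] == -1
        assert math.isnan(surface.mu[0, 0])


class TestSensitivities:
    def test_off_support_parameters_exactly_zero(self, branch_model, branch_efms):
        efm = next(e for e in branch_efms.biomass_producing(branch_model)
                   if "high_yield" in e.support)
        sol = minimize_enzyme_cost(efm, branch_model, Condition())
        report = growth_sensitivities(efm, sol, branch_model, Condition())
        off = report[report.reaction == "low_yield"]
        assert (off.dmu_dlnp == 0.0).all()

    def test_kcat_sum_rule(self, branch_model, branch_efms):
        # each E_r ~ 1/kcat_r at fixed x, so sum_r dEmet/dln kcat_r = -E_met
        efm = branch_efms.biomass_producing(branch_model).efms[0]
        sol = minimize_enzyme_cost(efm, branch_model, Condition())
        report = growth_sensitivities(efm, sol, branch_model, Condition())
        kcat_rows = report[report.parameter == "kcat_fwd"]
        assert kcat_rows.dEmet_dlnp.sum() == pytest.approx(-sol.e_met, rel=1e-9)

    def test_halved_kcat_compensation_prediction(self, chain_model, chain_efms):
        # Delta cost = (kcat_old/kcat_new - 1) * old reaction cost
        efm = chain_efms.efms[0]
        cond = Condition()
        sol = minimize_enzyme_cost(efm, chain_model, cond)
        from efcm.ecm import enzyme_demand

        rxn = "r1"
        old_cost = sol.cost_terms[rxn]
        kcat_old = chain_model.reaction(rxn).kinetics.kcat_fwd
        halved = Condition(param_overrides={(rxn, "kcat_fwd"): kcat_old / 2})
        d = enzyme_demand(efm.flux, sol.x, chain_model, halved)
        w = chain_model.reaction(rxn).kinetics.enzyme_mass
        assert w * d[rxn] - old_cost == pytest.approx(old_cost, rel=1e-12)

    @pytest.mark.parametrize("param", ["kcat_fwd", "keq", "km"])
    def test_envelope_matches_full_reoptimization(self, param, branch_model,
                                                  branch_efms):
        """Analytic d(mu)/d(ln p) vs central finite differences with re-solve."""
        efm = branch_efms.biomass_producing(branch_model).efms[0]
        cond = Condition()
        sol = minimize_enzyme_cost(efm, branch_model, cond)
        report = growth_sensitivities(efm, sol, branch_model, cond)
        rxn = sorted(efm.support - {"bm"})[0]
        if param == "km":
            met = sorted(branch_model.reaction(rxn).kinetics.km)[0]
            key, base = f"km:{met}", branch_model.reaction(rxn).kinetics.km[met]
        else:
            key = param
            base = getattr(branch_model.reaction(rxn).kinetics, param)
        analytic = float(
            report[(report.reaction == rxn) & (report.parameter == key)].dmu_dlnp.iloc[0]
        )
        h = 1e-4
        mus = []
        for fac in (math.exp(h), math.exp(-h)):
            over = Condition(param_overrides={(rxn, key if ":" in key else param):
                                              base * fac})
            s = minimize_enzyme_cost(efm, branch_model, over)
            mus.append(growth_rate_from_cost(s.e_met, branch_model.growth_params))
        numeric = (mus[0] - mus[1]) / (2 * h)
        assert analytic == pytest.approx(numeric, rel=1e-3, abs=1e-12)

    def test_external_concentration_sensitivity_sign(self, chain_model, chain_efms):
        # glucose appears only as a substrate: raising it can only help
        efm = chain_efms.efms[0]
        sol = minimize_enzyme_cost(efm, chain_model, Condition())
        report = growth_sensitivities(efm, sol, chain_model, Condition())
        row = report[report.parameter == "conc:glc_ext"]
        assert float(row.dmu_dlnp.iloc[0]) >= 0.0


class TestKnockouts:
    def test_unused_reaction_zero_advantage(self, branch_model, branch_efms,
                                            shared_cache):
        res = knockout_analysis(branch_model, branch_efms, {"high_yield"},
                                Condition(), cache=shared_cache)
        # the faster (low-yield) EFM survives, so the wild type gains nothing
        assert res["advantage"] == pytest.approx(0.0, abs=1e-12)

    def test_forcing_costly_route_gives_oracle_ratio(self, branch_model, branch_efms,
                                                     shared_cache):
        points, _ = rate_yield_spectrum(branch_efms, branch_model, Condition(),
                                        cache=shared_cache)
        mu = {p.efm_id: p.mu for p in points}
        low_id = next(p.efm_id for p in points if p.yield_g_per_cmol < 15)
        high_id = next(p.efm_id for p in points if p.yield_g_per_cmol > 15)
        res = knockout_analysis(branch_model, branch_efms, {"low_yield"}, Condition(),
                                spectrum=points)
        assert res["mu_wt"] == pytest.approx(mu[low_id])
        assert res["mu_ko"] == pytest.approx(mu[high_id])
        assert res["advantage"] == pytest.approx(mu[low_id] / mu[high_id] - 1.0)
        # the surviving strategy has the higher yield
        assert branch_efms[high_id].yield_g_per_cmol > branch_efms[
            low_id
        ].yield_g_per_cmol

    def test_sole_transporter_knockout_is_lethal(self, branch_model, branch_efms,
                                                 shared_cache):
        res = knockout_analysis(branch_model, branch_efms, {"upt"}, Condition(),
                                cache=shared_cache)
        assert math.isinf(res["advantage"]) and res["mu_ko"] == 0.0

    def test_mu_ko_never_exceeds_wildtype(self, branch_model, branch_efms,
                                          shared_cache):
        for ko in ({"low_yield"}, {"high_yield"}, {"upt"}, {"bm"}):
            res = knockout_analysis(branch_model, branch_efms, ko, Condition(),
                                    cache=shared_cache)
            assert res["mu_ko"] <= res["mu_wt"]
            assert res["advantage"] >= 0.0

    def test_unknown_reaction_rejected(self, branch_model, branch_efms):
        with pytest.raises(KeyError):
            knockout_analysis(branch_model, branch_efms, {"nope"}, Condition())


class TestEpistasis:
    def test_symmetry(self, branch_model, branch_efms, shared_cache):
        points, _ = rate_yield_spectrum(branch_efms, branch_model, Condition(),
                                        cache=shared_cache)
        ab = epistasis(branch_model, branch_efms, "low_yield", "high_yield",
                       Condition(), spectrum=points)
        ba = epistasis(branch_model, branch_efms, "high_yield", "low_yield",
                       Condition(), spectrum=points)
        assert math.isnan(ab["epsilon"]) == math.isnan(ba["epsilon"]) or (
            ab["epsilon"] == pytest.approx(ba["epsilon"])
        )

    def test_same_single_efm_reactions(self, branch_model, branch_efms, shared_cache):
        """Two reactions exclusive to the same EFM: mu_A = mu_B = mu_AB and
        eps = mu_wt / mu_A."""
        points, _ = rate_yield_spectrum(branch_efms, branch_model, Condition(),
                                        cache=shared_cache)
        # knock out high_yield twice-over by pairing it with itself via upt?
        # use the diamond: p1 and p2 are each exclusive to one EFM
        model = make_diamond_model(seed=9)
        efms = enumerate_efms(model)
        pts, _ = rate_yield_spectrum(efms, model, Condition())
        res = epistasis(model, efms, "p1", "p1", Condition(), spectrum=pts)
        assert res["mu_a"] == res["mu_b"] == res["mu_ab"]
        assert res["epsilon"] == pytest.approx(res["mu_wt"] / res["mu_a"])

    def test_lethal_pair_is_sentinel_aware(self, branch_model, branch_efms,
                                           shared_cache):
        points, _ = rate_yield_spectrum(branch_efms, branch_model, Condition(),
                                        cache=shared_cache)
        res = epistasis(branch_model, branch_efms, "upt", "bm", Condition(),
                        spectrum=points)
        assert math.isnan(res["epsilon"])
        assert res["mu_a"] == res["mu_b"] == res["mu_ab"] == 0.0
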