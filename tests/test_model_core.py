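"""State space, detailed balance, reaction-network structure, integration."""

import numpy as np
import pytest
from scipy.linalg import expm

from kaiac.kinetics import (
    SimulationCondition,
    build_reaction_rates,
    exchange_rate,
    observables,
    simulate,
    simulate_dephosphorylation_protocol,
)
from kaiac.params import (
    ALL_DELTA_NAMES,
    DERIVED_DELTA_NAMES,
    FREE_DELTA_NAMES,
    FREE_INIT_NAMES,
    N_FREE_PARAMS,
    RateParameterSet,
    apply_detailed_balance,
)
from kaiac.states import enumerate_states, state_index
from kaiac.synth import default_truth

from conftest import perturbed_params, random_delta_log10

# The four reversible cycles: (TP-state, DP-state) corner pairs; each walks
# C_TP^X -> C_DP^Y -> A-C_DP^Y -> A-C_TP^X -> back.
CYCLES = [("S", "D"), ("T", "D"), ("U", "T"), ("U", "S")]


def cycle_product_ratio(params: RateParameterSet, x: str, y: str) -> float:
    """Independent oracle: multiply the actual per-reaction rate constants
    around a cycle and return forward/reverse product ratio."""
    rxns = build_reaction_rates(params, SimulationCondition())
    rate = {}
    for r in rxns:
        rate[(r.source, r.target)] = r.rate
    ctpx = state_index(x, "TP", False)
    cdpy = state_index(y, "DP", False)
    actpx = state_index(x, "TP", True)
    acdpy = state_index(y, "DP", True)
    fwd = (
        rate[(ctpx, cdpy)] * rate[(cdpy, acdpy)] * rate[(acdpy, actpx)]
        * rate[(actpx, ctpx)]
    )
    rev = (
        rate[(ctpx, actpx)] * rate[(actpx, acdpy)] * rate[(acdpy, cdpy)]
        * rate[(cdpy, ctpx)]
    )
    return fwd / rev


class TestStateSpace:
    def test_sixteen_unique_states(self):
        states = enumerate_states()
        assert len(states) == 16
        assert len(set(states)) == 16
        assert sum(not s.kaiA_bound for s in states) == 8

    def test_dephosphorylation_endpoint_is_unique(self):
        hits = [
            s for s in enumerate_states()
            if s.phosphoform.value == "U" and s.nucleotide.value == "DP"
            and not s.kaiA_bound
        ]
        assert len(hits) == 1
        assert hits[0].index == state_index("U", "DP", False)

    def test_parameter_counts(self):
        assert len(FREE_DELTA_NAMES) == 34
        assert len(ALL_DELTA_NAMES) == 38
        assert len(DERIVED_DELTA_NAMES) == 4
        assert len(FREE_INIT_NAMES) == 7
        assert N_FREE_PARAMS == 48


class TestDetailedBalance:
    def test_symmetric_case_gives_unit_modifiers(self):
        derived = apply_detailed_balance({n: 0.0 for n in FREE_DELTA_NAMES})
        assert all(abs(v) < 1e-14 for v in derived.values())

    def test_cycle_products_close_for_random_modifiers(self, truth_params):
        rng = np.random.default_rng(42)
        for _ in range(50):
            params = RateParameterSet(
                base_rates=dict(truth_params.base_rates),
                delta_log10=random_delta_log10(rng),
            )
            for x, y in CYCLES:
                assert cycle_product_ratio(params, x, y) == pytest.approx(1.0, abs=1e-12)

    def test_each_cycle_has_one_dependent_modifier(self):
        base = {n: 0.1 for n in FREE_DELTA_NAMES}
        ref = apply_detailed_balance(base)
        # perturbing a modifier private to one cycle moves only that delta
        moved = dict(base, dkdA_TU=1.0)
        out = apply_detailed_balance(moved)
        changed = {k for k in ref if abs(out[k] - ref[k]) > 1e-12}
        assert changed == {"dka_T_DP"}

    def test_non_finite_input_rejected(self):
        bad = {n: 0.0 for n in FREE_DELTA_NAMES}
        bad["dkp_SD"] = float("nan")
        with pytest.raises(ValueError):
            apply_detailed_balance(bad)


class TestExchangeRate:
    @pytest.mark.parametrize(
        "kr,pct,expected", [(0.1, 100.0, 0.1), (0.1, 50.0, 0.05), (0.2, 1e-6, 2e-9)]
    )
    def test_linear_in_atp_fraction(self, kr, pct, expected):
        assert exchange_rate(kr, pct) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exchange_rate(-0.1, 50.0)
        with pytest.raises(ValueError):
            exchange_rate(0.1, 0.0)


@pytest.fixture(scope="module")
def reactions(truth_params):
    return build_reaction_rates(truth_params, SimulationCondition(pct_ATP=50.0))


class TestNetworkStructure:

    def test_no_dephosphorylation_from_atp_states(self, reactions):
        states = enumerate_states()
        order = {"U": 0, "T": 1, "S": 1, "D": 2}
        for r in reactions:
            if r.kind != "phosphotransfer":
                continue
            src, tgt = states[r.source], states[r.target]
            if order[tgt.phosphoform.value] < order[src.phosphoform.value]:
                # dephosphorylation arrow must leave an ADP-bound state
                assert src.nucleotide.value == "DP"
            else:
                assert src.nucleotide.value == "TP"

    def test_exchange_only_on_kaiA_bound_adp_states(self, reactions):
        states = enumerate_states()
        ex = [r for r in reactions if r.kind == "exchange"]
        assert len(ex) == 4
        for r in ex:
            assert states[r.source].kaiA_bound
            assert states[r.source].nucleotide.value == "DP"
            assert states[r.target].nucleotide.value == "TP"

    def test_exchange_carries_atp_fraction(self, truth_params):
        r100 = {
            (r.source, r.target): r.rate
            for r in build_reaction_rates(truth_params, SimulationCondition())
            if r.kind == "exchange"
        }
        r50 = {
            (r.source, r.target): r.rate
            for r in build_reaction_rates(
                truth_params, SimulationCondition(pct_ATP=50.0)
            )
            if r.kind == "exchange"
        }
        for key in r100:
            assert r50[key] == pytest.approx(0.5 * r100[key], rel=1e-12)

    def test_multiplicative_off_rate(self):
        params = default_truth().params
        delta = dict(params.delta_log10, dkb_T_TP=0.5)
        p = RateParameterSet(dict(params.base_rates, kb=0.0663), delta)
        off = {
            (r.source, r.target): r.rate
            for r in build_reaction_rates(p, SimulationCondition())
            if r.kind == "kaiA_off"
        }
        i = state_index("T", "TP", True)
        assert off[(i, i - 8)] == pytest.approx(0.0663 * 10 ** 0.5, rel=1e-12)


class TestIntegration:
    def test_mass_conservation_random_sets(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0.0, 48.0, 9)
        cond = SimulationCondition(kaiA_total_monomer=1.5, duration=48.0)
        for _ in range(3):
            params = perturbed_params(rng)
            traj = simulate(params, cond, t)
            total = traj.concentrations.sum(axis=0)
            assert np.abs(total - cond.kaiC_total).max() < 1e-6
            assert np.all(traj.free_kaiA_dimer >= -1e-9)
            assert traj.concentrations.min() > -1e-9

    def test_no_kaiA_dephosphorylates_to_cdpu(self, truth_params):
        # all mass starts doubly phosphorylated & ATP-bound, KaiA absent:
        # hydrolysis + phosphotransfer cycles must funnel to C_DP^U
        fracs = {n: 0.0 for n in FREE_INIT_NAMES}
        fracs["init_CTPD"] = 1.0
        params = RateParameterSet(
            base_rates=dict(truth_params.base_rates),
            delta_log10=dict(truth_params.delta_log10),
            init_fractions=fracs,
        )
        cond = SimulationCondition(kaiA_total_monomer=0.0, duration=200.0)
        traj = simulate(params, cond, np.array([0.0, 200.0]))
        cdpu = traj.concentrations[state_index("U", "DP", False), -1]
        assert cdpu / cond.kaiC_total > 0.99

    def test_pct_atp_irrelevant_without_kaiA(self, truth_params):
        fracs = dict(truth_params.init_fractions)
        t = np.linspace(0, 24, 5)
        outs = []
        for pct in (10.0, 100.0):
            cond = SimulationCondition(kaiA_total_monomer=0.0, pct_ATP=pct)
            outs.append(simulate(truth_params, cond, t).concentrations)
        np.testing.assert_allclose(outs[0], outs[1], rtol=0, atol=1e-9)

    def test_linear_subnetwork_matches_matrix_exponential(self, truth_params):
        # U-phosphoform-only subnetwork; KaiA in vast excess so binding is
        # pseudo-first-order and the 4-state system is linear
        kaiA_monomer = 2e6  # uM -> dimer 1e6, free KaiA constant to ~1e-8
        kaiC = 1e-2
        base = dict(truth_params.base_rates)
        base["kp"] = base["kd"] = 1e-30  # no phosphotransfer out of U
        base["ka"] = 1e-7  # on-flux ka * [A_dimer] ~ 0.1 s^-1
        fracs = {n: 0.0 for n in FREE_INIT_NAMES}
        fracs["init_CTPU"] = 1.0
        params = RateParameterSet(base, dict(truth_params.delta_log10),
                                  init_fractions=fracs)
        cond = SimulationCondition(
            kaiC_total=kaiC, kaiA_total_monomer=kaiA_monomer, pct_ATP=100.0
        )
        t = np.linspace(0.0, 10.0, 6)
        traj = simulate(params, cond, t, rtol=1e-11, atol=1e-14)

        idx = [state_index("U", n, b) for n in ("TP", "DP") for b in (False, True)]
        m = np.zeros((4, 4))
        pos = {s: k for k, s in enumerate(idx)}
        for r in build_reaction_rates(params, cond):
            if r.source not in pos or r.target not in pos:
                continue
            rate_h = r.rate * 3600.0
            if r.order == 2:
                rate_h *= cond.kaiA_dimer  # clamped free KaiA
            m[pos[r.source], pos[r.source]] -= rate_h
            m[pos[r.target], pos[r.source]] += rate_h
        y0 = np.zeros(4)
        y0[0] = kaiC
        for k, tk in enumerate(t):
            exact = expm(m * tk) @ y0
            np.testing.assert_allclose(
                traj.concentrations[idx, k], exact, rtol=0, atol=1e-8 * kaiC
            )

    def test_steady_state_cp_monotone_in_exchange_rate(self, truth_params):
        cond = SimulationCondition(kaiA_total_monomer=6.0, pct_ATP=100.0)
        t = np.array([0.0, 48.0])
        cps = []
        for scale in (0.3, 1.0, 3.0):
            base = dict(truth_params.base_rates)
            base["krDP"] *= scale
            p = RateParameterSet(base, dict(truth_params.delta_log10),
                                 init_fractions=dict(truth_params.init_fractions))
            cps.append(observables(simulate(p, cond, t)).pct["CP"][-1])
        assert cps[0] <= cps[1] + 1e-6 <= cps[2] + 2e-6


class TestDephosphorylationProtocol:
    def test_two_stage_bookkeeping_and_endpoint(self, truth_params):
        t = np.linspace(0.0, 48.0, 13)
        traj = simulate_dephosphorylation_protocol(truth_params, t)
        assert traj.kaiC_total < 3.4  # pull-down removed complexed KaiC
        assert np.abs(traj.concentrations.sum(axis=0) - traj.kaiC_total).max() < 1e-6
        # KaiA-bound states stay empty without KaiA
        assert np.abs(traj.concentrations[8:]).max() < 1e-9
        obs = observables(traj)
        assert obs.pct["U"][-1] > 95.0

    def test_independent_of_solution_atp(self, truth_params):
        t = np.linspace(0.0, 20.0, 5)
        a = simulate_dephosphorylation_protocol(truth_params, t)
        b = simulate_dephosphorylation_protocol(
            truth_params, t, SimulationCondition(pct_ATP=10.0)
        )
        np.testing.assert_allclose(a.concentrations, b.concentrations,
                                   rtol=0, atol=1e-9)


class TestObservables:
    def test_percentages_sum_to_100(self, truth_params):
        cond = SimulationCondition(kaiA_total_monomer=1.5)
        obs = observables(simulate(truth_params, cond, np.linspace(0, 24, 7)))
        total = sum(obs.pct[p] for p in "UTSD")
        np.testing.assert_allclose(total, 100.0, atol=1e-4)
        np.testing.assert_allclose(
            obs.pct["CP"], obs.pct["T"] + obs.pct["S"] + obs.pct["D"], atol=1e-12
        )

    def test_point_mass_in_cdpu(self, truth_params):
        fracs = {n: 0.0 for n in FREE_INIT_NAMES}
        fracs["init_CDPU"] = 1.0
        p = RateParameterSet(dict(truth_params.base_rates),
                             dict(truth_params.delta_log10), init_fractions=fracs)
        cond = SimulationCondition(kaiA_total_monomer=0.0)
        obs = observables(simulate(p, cond, np.array([0.0, 0.5])))
        assert obs.pct["U"][0] == pytest.approx(100.0, abs=1e-9)
        assert obs.pct["CP"][0] == pytest.approx(0.0, abs=1e-9)

    def test_no_adp_source_means_zero_production(self, truth_params):
        base = dict(truth_params.base_rates)
        base["kh"] = 1e-30
        base["kp"] = 1e-30
        fracs = {n: 0.0 for n in FREE_INIT_NAMES}
        fracs["init_CTPU"] = 1.0
        p = RateParameterSet(base, dict(truth_params.delta_log10),
                             init_fractions=fracs)
        cond = SimulationCondition(kaiA_total_monomer=1.5)
        obs = observables(simulate(p, cond, np.array([0.0, 12.0])))
        assert obs.adp_produced_12h == pytest.approx(0.0, abs=1e-6)
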