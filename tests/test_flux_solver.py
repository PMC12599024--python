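"""LP solver contract: FBA, parsimonious FBA and FVA.

The independent oracle for small problems is brute-force vertex enumeration
over the flux polytope {S v = 0, lb <= v <= ub}: every LP optimum is attained
at a vertex, and for <= 6 reactions all candidate vertices can be enumerated
by fixing subsets of variables at their bounds and solving the remaining
square system.
"""

import itertools

import numpy as np
import pytest

from glymal.flux_solver import fba, fva, pfba
from glymal.stoich_model import Metabolite, Reaction, StoichModel
from glymal.synthetic_data import toy_network


def enumerate_vertex_optimum(model):
    """Brute-force LP maximum over polytope vertices (oracle, <= ~8 rxns)."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    c = np.array([model.reactions[r].objective_coefficient for r in rxn_ids])
    n = len(rxn_ids)
    r = np.linalg.matrix_rank(S) if S.size else 0
    nfix = n - r
    best = None
    for fixed in itertools.combinations(range(n), nfix):
        free = [j for j in range(n) if j not in fixed]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, choice):
                v[j] = val
            rhs = -S[:, list(fixed)] @ np.array(choice) if fixed else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    return best


def random_toy_model(rng):
    """Random bounded network with <= 6 reactions and 0 in every bound box."""
    n_mets = rng.integers(2, 4)
    n_rxns = rng.integers(3, 7)
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        stoich = {}
        for i in range(n_mets):
            coef = rng.integers(-2, 3)
            if coef:
                stoich[f"m{i}_c"] = float(coef)
        if not stoich:
            stoich[f"m{rng.integers(0, n_mets)}_c"] = 1.0
        lo = float(rng.integers(-10, 1))
        hi = float(rng.integers(0, 11))
        obj = float(rng.integers(-1, 2))
        rxns.append(Reaction(f"r{j}", stoich, lower_bound=lo, upper_bound=hi,
                             objective_coefficient=obj))
    return StoichModel(mets, rxns, model_id="rand")


class TestFba:
    def test_bound_limited_chain(self):
        state = fba(toy_network("chain"))
        assert state.optimal
        assert state.objective_value == pytest.approx(10.0)
        assert state.fluxes["EX_A"] == pytest.approx(-10.0)

    def test_chain_without_uptake_gives_zero(self):
        m = toy_network("chain").with_bounds("EX_A", 0.0, 0.0)
        state = fba(m)
        assert state.optimal
        assert state.objective_value == pytest.approx(0.0)

    def test_infeasible_is_reported_not_raised(self):
        m = toy_network("chain").with_bounds("A2B", 5.0, 5.0)
        m = m.with_bounds("EX_A", 0.0, 0.0)
        state = fba(m)
        assert state.status == "infeasible"

    def test_matches_vertex_enumeration_on_random_networks(self):
        rng = np.random.default_rng(20240917)
        checked = 0
        for _ in range(40):
            model = random_toy_model(rng)
            oracle = enumerate_vertex_optimum(model)
            state = fba(model)
            if oracle is None:
                continue
            assert state.optimal
            assert state.objective_value == pytest.approx(oracle, abs=1e-6)
            checked += 1
        assert checked >= 30  # the generator keeps 0 feasible, so most solve

    def test_mass_balance_residual_on_core(self, m4_model):
        state = fba(m4_model.with_bounds("EX_glyc_e", -20.0, 0.0))
        S, met_ids, rxn_ids = m4_model.stoichiometric_matrix()
        v = np.array([state.fluxes[r] for r in rxn_ids])
        assert np.max(np.abs(S @ v)) <= 1e-6
        lb = np.array([m4_model.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([m4_model.reactions[r].upper_bound for r in rxn_ids])
        assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)


class TestPfba:
    def test_objective_matches_fba(self, m4_model):
        m = m4_model.with_bounds("EX_glyc_e", -20.0, 0.0)
        assert pfba(m).objective_value == pytest.approx(fba(m).objective_value, abs=1e-6)

    def test_diamond_routes_through_short_branch(self):
        state = pfba(toy_network("diamond"))
        assert state.fluxes["A2B"] == pytest.approx(10.0)
        assert state.fluxes["A2X"] == pytest.approx(0.0, abs=1e-9)

    def test_futile_cycle_is_zeroed(self):
        m = toy_network("futile_cycle")
        assert fba(m).objective_value == pytest.approx(10.0)
        state = pfba(m)
        assert state.objective_value == pytest.approx(10.0)
        assert state.fluxes["B2C"] == pytest.approx(0.0, abs=1e-9)
        assert state.fluxes["C2B"] == pytest.approx(0.0, abs=1e-9)

    def test_minimality_against_random_optimal_vertices(self):
        """No random flux vector attaining z* beats the pFBA total flux."""
        rng = np.random.default_rng(7)
        for name in ["diamond", "futile_cycle", "branched"]:
            model = toy_network(name)
            zstar = fba(model).objective_value
            best = pfba(model).total_absolute_flux
            S, _, rxn_ids = model.stoichiometric_matrix()
            for _ in range(100):
                # random vertex of the optimal face: optimize a random objective
                # subject to the original objective fixed at z*
                perturbed = model.copy()
                import dataclasses

                for rid in rxn_ids:
                    rxn = perturbed.reactions[rid]
                    perturbed.reactions[rid] = dataclasses.replace(
                        rxn, objective_coefficient=float(rng.normal())
                    )
                from glymal.flux_solver import _lp_parts, _solve_lp

                Sm, rids, lb, ub, c_r = _lp_parts(perturbed)
                c0 = np.array(
                    [model.reactions[r].objective_coefficient for r in rids]
                )
                import scipy.sparse as sp

                A_eq = sp.vstack([Sm, sp.csr_matrix(c0.reshape(1, -1))])
                b_eq = np.concatenate([np.zeros(Sm.shape[0]), [zstar]])
                res, status = _solve_lp(-c_r, A_eq, b_eq, list(zip(lb, ub)))
                assert status == "optimal"
                assert np.abs(res.x).sum() >= best - 1e-6

    def test_no_objective_minimizes_total_flux_directly(self):
        m = toy_network("chain")
        m = m.with_bounds("EX_A", -4.0, -4.0)  # forced throughput, no objective
        import dataclasses

        m.reactions["EX_B"] = dataclasses.replace(
            m.reactions["EX_B"], objective_coefficient=0.0
        )
        state = pfba(m)
        assert state.optimal
        assert state.total_absolute_flux == pytest.approx(12.0)  # 4+4+4


class TestFva:
    def test_fully_determined_network_collapses(self):
        m = toy_network("chain").with_bounds("EX_A", -10.0, -10.0)
        m = m.with_bounds("EX_B", 10.0, 10.0)
        ranges = fva(m, ["EX_A", "A2B", "EX_B"])
        for lo, hi in ranges.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-7)

    def test_sandwiches_pfba(self, m4_model):
        m = m4_model.with_bounds("EX_glyc_e", -20.0, 0.0)
        state = pfba(m)
        panel = ["ATPS4r", "PGK", "GAPD", "PPCK", "PDH"]
        ranges = fva(m, panel, fraction_of_optimum=1.0)
        for rid in panel:
            lo, hi = ranges[rid]
            assert lo - 1e-6 <= state.fluxes[rid] <= hi + 1e-6

    def test_unknown_reaction_raises(self, m4_model):
        with pytest.raises(KeyError, match="NOT_THERE"):
            fva(m4_model, ["NOT_THERE"])


@pytest.fixture(scope="module")
def cobra_pair(m4_model, tmp_path_factory):
    cobra = pytest.importorskip("cobra")
    from glymal.stoich_model import write_bigg_json

    m = m4_model.with_bounds("EX_glyc_e", -20.0, 0.0)
    p = tmp_path_factory.mktemp("xval") / "m4.json"
    write_bigg_json(m, p)
    cm = cobra.io.load_json_model(str(p))
    return m, cm


class TestCobraCrossValidation:
    """Oracle equivalence with an established constraint-based package."""

    def test_fba_objective_agrees(self, cobra_pair):
        mine, cm = cobra_pair
        assert fba(mine).objective_value == pytest.approx(
            cm.optimize().objective_value, abs=1e-4
        )

    def test_pfba_panel_fluxes_agree(self, cobra_pair):
        from cobra.flux_analysis import pfba as cobra_pfba

        mine, cm = cobra_pair
        ours = pfba(mine)
        theirs = cobra_pfba(cm)
        for rid in ["BIOMASS_Ecoli_core_w_GAM", "EX_glyc_e", "EX_o2_e", "EX_co2_e"]:
            assert ours.fluxes[rid] == pytest.approx(theirs.fluxes[rid], abs=1e-4)
        assert ours.total_absolute_flux == pytest.approx(
            float(theirs.fluxes.abs().sum()), abs=1e-3
        )

    def test_fva_ranges_agree(self, cobra_pair):
        from cobra.flux_analysis import flux_variability_analysis as cobra_fva

        mine, cm = cobra_pair
        panel = ["ATPS4r", "PPCK", "GAPD"]
        ours = fva(mine, panel, fraction_of_optimum=1.0)
        theirs = cobra_fva(cm, panel, fraction_of_optimum=1.0)
        for rid in panel:
            assert ours[rid][0] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-4)
            assert ours[rid][1] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-4)
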