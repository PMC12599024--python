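"""Flux balance analysis, parsimonious FBA and flux variability analysis.

All three operate on the LP contract ``maximize c.v subject to S.v = 0,
lb <= v <= ub`` and are built on scipy's HiGHS backend through one narrow
entry point (:func:`_solve_lp`), so the solver is swappable.

pFBA follows the two-stage scheme: stage 1 finds the optimal objective z*;
stage 2 minimizes the total absolute flux sum |v| (via split non-negative
forward/backward auxiliaries) with the objective pinned at z* as an equality.
When the model has no objective — the scenario case where every measured
exchange is already fixed — the total absolute flux is minimized directly.

FVA reports per-reaction (min, max) flux over the feasible region with the
objective held at ``fraction_of_optimum`` x z*; the optional ``pfba_factor``
additionally caps the total absolute flux at ``pfba_factor`` x its pFBA
minimum, restricting the search to the parsimonious face.  The published
flux-range claims for the Pck strains are statements about that face.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, hstack, identity

from .stoich_model import FluxState, StoichModel

__all__ = ["fba", "pfba", "fva", "FEASIBILITY_TOL", "COMPARISON_TOL"]

FEASIBILITY_TOL = 1e-9
COMPARISON_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    """Minimize c.x; thin wrapper so the LP backend stays swappable."""
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _STATUS.get(res.status, "numerical")
    return res, status


def _lp_parts(model: StoichModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    c = np.array([model.reactions[r].objective_coefficient for r in rxn_ids])
    return csr_matrix(S), rxn_ids, lb, ub, c


def fba(model: StoichModel) -> FluxState:
    """Maximize the model objective; a model without objective is solved as a
    feasibility problem with objective 0."""
    S, rxn_ids, lb, ub, c = _lp_parts(model)
    res, status = _solve_lp(-c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    if status != "optimal":
        return FluxState({}, float("nan"), status)
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxState(
        fluxes,
        float(c @ res.x),
        "optimal",
        total_absolute_flux=float(np.abs(res.x).sum()),
    )


def _min_total_flux(S, lb, ub, extra_eq_row=None, extra_eq_val=None):
    """Minimize sum |v| over {S v = 0, lb<=v<=ub [, row.v = val]}.

    Splits v = p - q with p, q >= 0 and minimizes sum(p + q): variables are
    [v, p, q] with the coupling v - p + q = 0, which keeps arbitrary (even
    fixed-negative) bounds on v intact.
    """
    m, n = S.shape
    Z = csr_matrix((m, n))
    rows = [hstack([S, Z, Z])]
    rhs = [np.zeros(m)]
    rows.append(hstack([identity(n), -identity(n), identity(n)]))
    rhs.append(np.zeros(n))
    if extra_eq_row is not None:
        rows.append(hstack([csr_matrix(extra_eq_row.reshape(1, -1)),
                            csr_matrix((1, 2 * n))]))
        rhs.append(np.array([extra_eq_val]))
    from scipy.sparse import vstack

    A_eq = vstack(rows, format="csr")
    b_eq = np.concatenate(rhs)
    bounds = list(zip(lb, ub)) + [(0, None)] * (2 * n)
    cost = np.concatenate([np.zeros(n), np.ones(2 * n)])
    res, status = _solve_lp(cost, A_eq, b_eq, bounds)
    return res, status, n


def pfba(model: StoichModel) -> FluxState:
    """Parsimonious FBA.

    With an objective: fix it at its FBA optimum (equality, no slack) and
    minimize total absolute flux.  Without one: minimize total absolute flux
    over the feasible region directly.
    """
    S, rxn_ids, lb, ub, c = _lp_parts(model)
    has_obj = np.any(c != 0)
    zstar = 0.0
    if has_obj:
        stage1 = fba(model)
        if not stage1.optimal:
            return stage1
        zstar = stage1.objective_value
    res, status, n = _min_total_flux(
        S, lb, ub,
        extra_eq_row=c if has_obj else None,
        extra_eq_val=zstar if has_obj else None,
    )
    if status != "optimal":
        return FluxState({}, float("nan"), status)
    v = res.x[:n]
    return FluxState(
        dict(zip(rxn_ids, v)),
        float(c @ v) if has_obj else 0.0,
        "optimal",
        total_absolute_flux=float(np.abs(v).sum()),
    )


def fva(
    model: StoichModel,
    reaction_ids: list[str],
    fraction_of_optimum: float = 1.0,
    pfba_factor: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux ranges at (near-)optimal objective.

    The objective constraint ``c.v >= fraction * z*`` is omitted when the
    model has no objective.  ``pfba_factor`` (e.g. 1.0) additionally bounds
    sum |v| by that multiple of the pFBA minimum.
    """
    for rid in reaction_ids:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction {rid!r}")
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    S, rxn_ids, lb, ub, c = _lp_parts(model)
    m, n = S.shape
    has_obj = np.any(c != 0)

    A_ub_rows, b_ub = [], []
    if has_obj:
        base = fba(model)
        if not base.optimal:
            raise RuntimeError(f"FVA base problem is {base.status}")
        A_ub_rows.append(-c.reshape(1, -1))
        b_ub.append(-fraction_of_optimum * base.objective_value)

    index = {r: j for j, r in enumerate(rxn_ids)}

    if pfba_factor is None:
        A_ub = np.vstack(A_ub_rows) if A_ub_rows else None
        b_arr = np.array(b_ub) if b_ub else None
        out = {}
        for rid in reaction_ids:
            j = index[rid]
            lohi = []
            for sign in (1.0, -1.0):
                cost = np.zeros(n)
                cost[j] = sign
                res, status = _solve_lp(cost, S, np.zeros(m), list(zip(lb, ub)),
                                        A_ub=A_ub, b_ub=b_arr)
                if status != "optimal":
                    raise RuntimeError(f"FVA subproblem for {rid} is {status}")
                lohi.append(float(res.x[j]))
            out[rid] = (lohi[0], lohi[1])
        return out

    # parsimonious-face FVA: augment with split variables and cap sum |v|
    base_p = pfba(model)
    if not base_p.optimal:
        raise RuntimeError(f"pFBA base problem is {base_p.status}")
    from scipy.sparse import vstack

    Z = csr_matrix((m, n))
    A_eq = vstack(
        [hstack([S, Z, Z]), hstack([identity(n), -identity(n), identity(n)])],
        format="csr",
    )
    b_eq = np.zeros(m + n)
    ub_rows = [np.concatenate([np.zeros(n), np.ones(2 * n)]).reshape(1, -1)]
    ub_vals = [pfba_factor * base_p.total_absolute_flux + COMPARISON_TOL]
    if has_obj:
        zstar = base_p.objective_value
        ub_rows.append(np.concatenate([-c, np.zeros(2 * n)]).reshape(1, -1))
        ub_vals.append(-fraction_of_optimum * zstar)
    A_ub = np.vstack(ub_rows)
    b_arr = np.array(ub_vals)
    bounds = list(zip(lb, ub)) + [(0, None)] * (2 * n)
    out = {}
    for rid in reaction_ids:
        j = index[rid]
        lohi = []
        for sign in (1.0, -1.0):
            cost = np.zeros(3 * n)
            cost[j] = sign
            res, status = _solve_lp(cost, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_arr)
            if status != "optimal":
                raise RuntimeError(f"FVA subproblem for {rid} is {status}")
            lohi.append(float(res.x[j]))
        out[rid] = (lohi[0], lohi[1])
    return out
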