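"""Constraint-based analysis of community models.

Flux balance analysis (FBA), parsimonious FBA, flux variability analysis
(FVA) and hit-and-run flux sampling over the guild-compartmentalized
stoichiometric model, plus the proteome-share ATP constraint that couples
the three guilds.

The linear programs are solved with the HiGHS solver via
:func:`scipy.optimize.linprog`.  All solutions satisfy the steady-state
constraint ``S v = 0`` to 1e-8 (asserted), and, when proteome constraints
are active, the per-guild ATP-yield shares to 1e-6.

Proteome-share ATP coupling
---------------------------
The guilds' relative catabolic ATP yields are constrained to their relative
proteome contributions: with ``y_g`` the flux through guild g's ATP sink and
``s_g`` the normalized proteome share, the linear rows

    y_g - s_g * sum_h y_h = 0        for every guild g

are appended to the equality system.  This linearizes the ratio constraint
exactly, and any solution has per-guild ATP shares equal to ``s_g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .network import CommunityModel

__all__ = [
    "FluxSolution",
    "apply_proteome_atp_constraints",
    "fba",
    "pfba",
    "fva",
    "flux_sample",
    "scenario_drop_guild",
    "community_yield",
]

_FEAS_TOL = 1e-9
_STEADY_TOL = 1e-8


@dataclass
class FluxSolution:
    """A solved flux distribution on the 1-mol-acetate basis."""

    fluxes: pd.Series
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded
    model_name: str = ""
    guild_net_stoichiometry: dict[str, dict[str, float]] = field(default_factory=dict)
    atp_per_guild: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def apply_proteome_atp_constraints(
    model: CommunityModel, shares: dict[str, float]
) -> CommunityModel:
    """Return a copy of the model with guild ATP yields pinned to shares.

    ``shares`` maps guild -> proteome fraction; values are renormalized to
    sum to 1 over the guilds present in the model.  Every guild in the model
    must receive a positive share.
    """
    out = model.copy()
    missing = set(out.guilds) - set(shares)
    if missing:
        raise KeyError(f"no proteome share for guild(s) {sorted(missing)}")
    sub = {g: float(shares[g]) for g in out.guilds}
    if any(v <= 0 for v in sub.values()):
        raise ValueError("proteome shares must be positive")
    total = sum(sub.values())
    out.proteome_shares = {g: v / total for g, v in sub.items()}
    return out


def _build_equalities(model: CommunityModel):
    """Stack S v = 0 with the proteome ATP-share rows (if any)."""
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    rows = [S]
    if model.proteome_shares:
        sinks = model.atp_sinks
        missing = set(model.proteome_shares) - set(sinks)
        if missing:
            raise ValueError(f"guild(s) {sorted(missing)} lack an ATP sink reaction")
        pos = {r: j for j, r in enumerate(rxn_ids)}
        sink_cols = {g: pos[sinks[g]] for g in model.proteome_shares}
        for g, s in model.proteome_shares.items():
            row = np.zeros(len(rxn_ids))
            for col in sink_cols.values():
                row[col] -= s
            row[sink_cols[g]] += 1.0
            rows.append(row.reshape(1, -1))
    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rxn_ids
    ]
    return A_eq, b_eq, bounds, rxn_ids


def _objective_vector(model: CommunityModel, objective, rxn_ids) -> np.ndarray:
    if objective is None:
        objective = model.default_objective()
    c = np.zeros(len(rxn_ids))
    pos = {r: j for j, r in enumerate(rxn_ids)}
    for rid, w in objective.items():
        if rid not in pos:
            raise KeyError(f"objective reaction {rid!r} not in model")
        c[pos[rid]] = w
    return c


def _finish_solution(model, rxn_ids, x, objective_value) -> FluxSolution:
    fluxes = pd.Series(x, index=rxn_ids, name="flux")
    sol = FluxSolution(
        fluxes=fluxes,
        objective_value=objective_value,
        status="optimal",
        model_name=model.name,
    )
    sol.atp_per_guild = {
        g: float(fluxes[rid]) for g, rid in model.atp_sinks.items()
    }
    sol.guild_net_stoichiometry = _guild_net_stoichiometry(model, fluxes)
    # steady-state assertion on the metabolite rows only
    S, _, _ = model.stoichiometric_matrix()
    resid = np.abs(S @ x).max() if len(x) else 0.0
    if resid > _STEADY_TOL:
        raise RuntimeError(f"solution violates steady state (|Sv|max = {resid:g})")
    return sol


def _guild_net_stoichiometry(model, fluxes) -> dict[str, dict[str, float]]:
    """Net production (+) / consumption (-) of extracellular species per guild."""
    ext = {m for m, met in model.metabolites.items() if met.compartment == "e"}
    out: dict[str, dict[str, float]] = {g: {} for g in model.guilds}
    for rid, rxn in model.reactions.items():
        if rxn.guild not in out:
            continue
        v = float(fluxes[rid])
        for met, coeff in rxn.stoichiometry.items():
            if met in ext:
                short = met[: met.index("[")]
                out[rxn.guild][short] = out[rxn.guild].get(short, 0.0) + coeff * v
    for g in out:
        out[g] = {k: v for k, v in out[g].items() if abs(v) > 1e-9}
    return out


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def fba(model: CommunityModel, objective: dict[str, float] | None = None) -> FluxSolution:
    """Maximize the objective (default: total community ATP yield).

    Infeasible or unbounded problems are surfaced in ``FluxSolution.status``,
    never silently.
    """
    A_eq, b_eq, bounds, rxn_ids = _build_equalities(model)
    c = _objective_vector(model, objective, rxn_ids)
    res = linprog(-c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return FluxSolution(
            fluxes=pd.Series(np.nan, index=rxn_ids),
            objective_value=None,
            status=_STATUS.get(res.status, "failed"),
            model_name=model.name,
        )
    return _finish_solution(model, rxn_ids, res.x, float(c @ res.x))


def pfba(model: CommunityModel, objective: dict[str, float] | None = None) -> FluxSolution:
    """Parsimonious FBA: among optimal flux vectors, minimize total |flux|.

    The FBA optimum is fixed as an exact equality constraint, fluxes are
    split into forward/backward non-negative parts, and the summed parts are
    minimized.  The reported objective equals the FBA optimum to 1e-9.
    """
    first = fba(model, objective)
    if not first.ok:
        return first
    A_eq, b_eq, bounds, rxn_ids = _build_equalities(model)
    c = _objective_vector(model, objective, rxn_ids)
    n = len(rxn_ids)
    # v = p - q with p, q >= 0; minimize sum(p + q)
    A_split = np.hstack([A_eq, -A_eq])
    obj_row = np.hstack([c, -c]).reshape(1, -1)
    A_all = np.vstack([A_split, obj_row])
    b_all = np.concatenate([b_eq, [first.objective_value]])
    split_bounds = []
    for lb, ub in bounds:
        split_bounds.append((max(0.0, lb), max(0.0, ub)))  # p
    for lb, ub in bounds:
        split_bounds.append((max(0.0, -ub), max(0.0, -lb)))  # q
    cost = np.ones(2 * n)
    res = linprog(cost, A_eq=A_all, b_eq=b_all, bounds=split_bounds, method="highs")
    if res.status != 0:
        # fall back to the FBA solution rather than failing silently
        return first
    v = res.x[:n] - res.x[n:]
    obj_val = float(c @ v)
    if abs(obj_val - first.objective_value) > 1e-9 * max(1.0, abs(first.objective_value)):
        raise RuntimeError("pFBA failed to hold the FBA optimum fixed")
    return _finish_solution(model, rxn_ids, v, obj_val)


def fva(
    model: CommunityModel,
    objective: dict[str, float] | None = None,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-reaction (min, max) flux at >= fraction of the objective optimum."""
    first = fba(model, objective)
    if not first.ok:
        raise RuntimeError(f"FVA requires a solvable model (status: {first.status})")
    A_eq, b_eq, bounds, rxn_ids = _build_equalities(model)
    c = _objective_vector(model, objective, rxn_ids)
    # objective >= fraction * optimum, with a hair of slack for LP numerics
    target = fraction_of_optimum * first.objective_value
    A_ub = (-c).reshape(1, -1)
    b_ub = np.array([-(target - 1e-9 * max(1.0, abs(target)))])
    which = reactions if reactions is not None else rxn_ids
    pos = {r: j for j, r in enumerate(rxn_ids)}
    rows = []
    for rid in which:
        e = np.zeros(len(rxn_ids))
        e[pos[rid]] = 1.0
        lo = linprog(e, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                     bounds=bounds, method="highs")
        hi = linprog(-e, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                     bounds=bounds, method="highs")
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem failed for {rid!r}")
        rows.append((rid, float(lo.fun), float(-hi.fun)))
    return pd.DataFrame(rows, columns=["rxn_id", "min", "max"]).set_index("rxn_id")


def flux_sample(
    model: CommunityModel,
    n: int,
    seed: int,
    thin: int = 100,
) -> pd.DataFrame:
    """Coordinate-free hit-and-run sampling of the steady-state flux polytope.

    Samples satisfy ``S v = 0`` (and active proteome constraints) to 1e-6 and
    the bounds.  The chain starts from the centroid of the FVA vertex
    solutions (a feasible interior-leaning point by convexity), takes
    ``thin`` random chord steps per retained sample, and is fully determined
    by ``seed``.  Unbounded directions raise.
    """
    A_eq, b_eq, bounds, rxn_ids = _build_equalities(model)
    lbs = np.array([b[0] for b in bounds])
    ubs = np.array([b[1] for b in bounds])
    if not (np.isfinite(lbs).all() and np.isfinite(ubs).all()):
        raise ValueError("flux sampling requires finite bounds on all reactions")

    # start point: average of all FVA extreme solutions
    c0 = np.zeros(len(rxn_ids))
    pts = []
    for j in range(len(rxn_ids)):
        for sign in (1.0, -1.0):
            e = c0.copy()
            e[j] = sign
            res = linprog(e, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
            if res.status == 3:
                raise ValueError("feasible region is unbounded")
            if res.status != 0:
                raise RuntimeError(f"sampling pre-solve failed (status {res.status})")
            pts.append(res.x)
    v = np.mean(pts, axis=0)

    # null-space basis of the equality system
    _, s, vt = np.linalg.svd(A_eq)
    rank = int((s > 1e-10 * s[0]).sum()) if s.size else 0
    N = vt[rank:].T  # columns span null space
    rng = np.random.default_rng(seed)
    samples = np.empty((n, len(rxn_ids)))
    if N.shape[1] == 0:  # unique solution
        samples[:] = v
        return pd.DataFrame(samples, columns=rxn_ids)
    for i in range(n):
        for _ in range(thin):
            w = rng.standard_normal(N.shape[1])
            d = N @ w
            norm = np.linalg.norm(d)
            if norm < 1e-12:
                continue
            d /= norm
            with np.errstate(divide="ignore", invalid="ignore"):
                t_lo = (lbs - v) / d
                t_hi = (ubs - v) / d
            t_min = np.where(d > 1e-12, t_lo, np.where(d < -1e-12, t_hi, -np.inf)).max()
            t_max = np.where(d > 1e-12, t_hi, np.where(d < -1e-12, t_lo, np.inf)).min()
            if t_max <= t_min:
                continue
            v = v + rng.uniform(t_min, t_max) * d
        samples[i] = v
    out = pd.DataFrame(samples, columns=rxn_ids)
    resid = np.abs(out.to_numpy() @ A_eq.T).max()
    if resid > 1e-6:
        raise RuntimeError(f"sampler drifted off the constraint manifold ({resid:g})")
    return out


def scenario_drop_guild(model: CommunityModel, guild: str) -> CommunityModel:
    """Community model without one guild (shares renormalized).

    Thin wrapper over :meth:`CommunityModel.drop_guild`; solving the reduced
    model may legitimately return an infeasible status (e.g. when the sole
    acetate oxidizer is removed).
    """
    return model.drop_guild(guild)


def community_yield(sol: FluxSolution) -> dict:
    """Summarize a solved community flux distribution.

    Returns total and per-guild ATP yields (mol ATP per mol acetate), each
    guild's net exchange stoichiometry, and the share of methane produced by
    each methanogen (summing to 1 over CH4 producers).
    """
    if not sol.ok:
        raise ValueError(f"cannot summarize a non-optimal solution ({sol.status})")
    ch4 = {
        g: net.get("ch4", 0.0)
        for g, net in sol.guild_net_stoichiometry.items()
        if net.get("ch4", 0.0) > 0
    }
    ch4_total = sum(ch4.values())
    return {
        "atp_total": sum(sol.atp_per_guild.values()),
        "atp_per_guild": dict(sol.atp_per_guild),
        "net_stoichiometry": {g: dict(v) for g, v in sol.guild_net_stoichiometry.items()},
        "ch4_share": {g: v / ch4_total for g, v in ch4.items()} if ch4_total > 0 else {},
    }
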