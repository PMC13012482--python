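"""Mixed-integer pooling model: assign bottles to ~2-L pools so the pooled
crude protein and energy sit as close as possible to the bank's targets.

Formulation
-----------
Sets: available bottles ``b`` (each with volume ``v_b`` mL and predicted
composition ``c_bn`` per 100 mL), their donors ``d``, pools ``p`` (a fixed
count), nutrients ``n`` in {protein, energy} with targets ``T_n``.

Binary ``x[b,p]`` picks bottle ``b`` for pool ``p``; binary ``y[d,p]`` marks
donor ``d`` as used in pool ``p``.  Constraints: each bottle in at most one
pool; pool volume within [vmin, vmax]; distinct donors per pool within
[min_donors, max_donors]; ``x[b,p] <= y[donor(b),p]`` and
``y[d,p] <= sum_b x[b,p]`` so donor counts are exact.

The absolute deviation of pool nutrient mass from target is linearised with
nonnegative slacks ``dplus/dminus``:

    dplus[p,n] - dminus[p,n] = sum_b (v_b/100) c_bn x[b,p]
                               - (T_n/100) sum_b v_b x[b,p]

and the objective is

    sum_{p,n} (dplus[p,n] + dminus[p,n]) / (T_n * Vref/100)
    - w_prio * sum_{b,p} u_b x[b,p]

where ``Vref`` (2000 mL) is a fixed normalisation volume that keeps the
model linear and makes the two nutrients commensurate, and ``u_b`` in [0,1]
is an expiry urgency (1 at expiry, 0 a full storage period away).  The tiny
weight ``w_prio`` makes expiry prioritisation epsilon-lexicographic: it
breaks deviation ties toward urgent bottles without trading deviation for
urgency.  Exact normalised deviations (|c_pool - T_n| / T_n, using the
realised pool volume) are always recomputed post hoc by
:func:`evaluate_assignment`.

Solved with the HiGHS branch-and-bound solver (``scipy.optimize.milp``);
every returned assignment is independently audited against all constraints
rather than trusting solver status, and a hand-written exhaustive oracle
(:func:`brute_force_oracle`) verifies optimality on small instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .exceptions import (
    EnumerationBoundError,
    InfeasibleError,
    ReferentialError,
    ValidationError,
)
from .records import BottleRecord, PoolingConfig, PoolRecord

__all__ = [
    "MilpModel",
    "PoolAssignment",
    "build_model",
    "solve",
    "brute_force_oracle",
    "evaluate_assignment",
    "suggest_n_pools",
    "contents_table",
]

NUTRIENTS = ("protein", "energy")


def contents_table(bottles: list[BottleRecord], predictions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-bottle composition table (g or kcal per 100 mL) for the model.

    With ``predictions`` (columns bottle_id, pred_protein, pred_energy) the
    predicted values are used; otherwise each bottle's own composition
    fields.  A bottle without a composition raises ``ValidationError``.
    """
    if predictions is not None:
        pred = predictions.set_index("bottle_id")
        missing = [b.bottle_id for b in bottles if b.bottle_id not in pred.index]
        if missing:
            raise ValidationError(
                f"missing prediction for bottle(s): {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )
        return pd.DataFrame(
            {
                "bottle_id": [b.bottle_id for b in bottles],
                "protein": [float(pred.at[b.bottle_id, "pred_protein"]) for b in bottles],
                "energy": [float(pred.at[b.bottle_id, "pred_energy"]) for b in bottles],
            }
        )
    for b in bottles:
        if b.crude_protein is None or b.energy is None:
            raise ValidationError(
                f"bottle {b.bottle_id} has no composition and no prediction was given"
            )
    return pd.DataFrame(
        {
            "bottle_id": [b.bottle_id for b in bottles],
            "protein": [b.crude_protein for b in bottles],
            "energy": [b.energy for b in bottles],
        }
    )


@dataclass
class MilpModel:
    """Assembled model: variable layout, constraint system, objective."""

    bottles: list[BottleRecord]
    config: PoolingConfig
    contents: pd.DataFrame            # bottle_id, protein, energy (per 100 mL)
    urgency: np.ndarray               # u_b in [0, 1]
    donors: list[str]                 # distinct donor ids, fixed order
    constraints: LinearConstraint
    objective: np.ndarray
    integrality: np.ndarray
    bounds: Bounds
    n_x: int = 0
    n_y: int = 0

    @property
    def n_pools(self) -> int:
        return self.config.n_pools

    def x_index(self, b: int, p: int) -> int:
        return b * self.n_pools + p

    def y_index(self, d: int, p: int) -> int:
        return self.n_x + d * self.n_pools + p


def _deviation_norms(config: PoolingConfig) -> dict[str, float]:
    """Objective denominators T_n * Vref / 100 (grams / kcal at target)."""
    return {
        "protein": config.target_protein * config.reference_volume_ml / 100.0,
        "energy": config.target_energy * config.reference_volume_ml / 100.0,
    }


def compute_urgency(bottles: list[BottleRecord], config: PoolingConfig, asof: date) -> np.ndarray:
    """Expiry urgency u_b = 1 - days_to_expiry / storage_limit, clipped to [0, 1]."""
    days = np.array([(b.expiry_date - asof).days for b in bottles], dtype=float)
    return np.clip(1.0 - days / config.storage_limit_days, 0.0, 1.0)


def build_model(
    bottles: list[BottleRecord],
    config: PoolingConfig,
    predictions: pd.DataFrame | None = None,
    asof: date | None = None,
    uncertainty=None,
) -> MilpModel:
    """Assemble the pooling MILP for the available bottles.

    ``asof`` is the pooling date used for expiry urgency (defaults to the
    latest arrival among the bottles).  Passing an
    :class:`~milkpool.robustness.UncertaintySet` as ``uncertainty`` switches
    the objective to its min-max robust counterpart: the worst-case absolute
    deviation over the composition box is the nominal deviation plus the
    (linear) total half-width of the selected bottles, so robust
    re-optimisation stays a MILP.
    """
    if not bottles:
        raise ValidationError("no bottles available to pool")
    if config.n_pools < 1:
        raise ValidationError("n_pools must be >= 1")
    contents = contents_table(bottles, predictions)
    asof = asof or max(b.arrival_date for b in bottles)
    urgency = compute_urgency(bottles, config, asof)

    total_volume = sum(b.volume_ml for b in bottles)
    if config.n_pools * config.vmin_ml > total_volume:
        warnings.warn(
            f"likely infeasible: {config.n_pools} pool(s) need at least "
            f"{config.n_pools * config.vmin_ml:.0f} mL but only "
            f"{total_volume:.0f} mL is available",
            stacklevel=2,
        )

    B, P = len(bottles), config.n_pools
    donors = sorted({b.donor_id for b in bottles})
    D = len(donors)
    donor_idx = {d: i for i, d in enumerate(donors)}
    n_x, n_y, n_slack = B * P, D * P, 2 * P * 2  # dplus and dminus per pool/nutrient
    n_var = n_x + n_y + n_slack

    def xi(b, p):
        return b * P + p

    def yi(d, p):
        return n_x + d * P + p

    def dplus_i(p, k):  # k: nutrient index
        return n_x + n_y + (p * 2 + k) * 2

    volumes = np.array([b.volume_ml for b in bottles])
    comp = contents[["protein", "energy"]].to_numpy()
    targets = np.array([config.target_protein, config.target_energy])
    norms = _deviation_norms(config)

    rows, cols, vals = [], [], []
    lb, ub = [], []
    r = 0

    # each bottle in at most one pool
    for b in range(B):
        for p in range(P):
            rows.append(r), cols.append(xi(b, p)), vals.append(1.0)
        lb.append(-np.inf), ub.append(1.0)
        r += 1
    # pool volume window
    for p in range(P):
        for b in range(B):
            rows.append(r), cols.append(xi(b, p)), vals.append(volumes[b])
        lb.append(config.vmin_ml), ub.append(config.vmax_ml)
        r += 1
    # donor count window
    for p in range(P):
        for d in range(D):
            rows.append(r), cols.append(yi(d, p)), vals.append(1.0)
        lb.append(float(config.min_donors)), ub.append(float(config.max_donors))
        r += 1
    # x <= y (a used bottle activates its donor)
    for b in range(B):
        d = donor_idx[bottles[b].donor_id]
        for p in range(P):
            rows.append(r), cols.append(xi(b, p)), vals.append(1.0)
            rows.append(r), cols.append(yi(d, p)), vals.append(-1.0)
            lb.append(-np.inf), ub.append(0.0)
            r += 1
    # y <= sum x (an active donor contributes at least one bottle)
    donor_bottles: dict[int, list[int]] = {}
    for b in range(B):
        donor_bottles.setdefault(donor_idx[bottles[b].donor_id], []).append(b)
    for d in range(D):
        for p in range(P):
            rows.append(r), cols.append(yi(d, p)), vals.append(1.0)
            for b in donor_bottles[d]:
                rows.append(r), cols.append(xi(b, p)), vals.append(-1.0)
            lb.append(-np.inf), ub.append(0.0)
            r += 1
    # deviation linking: dplus - dminus = nutrient mass - target mass
    for p in range(P):
        for k in range(2):
            i_plus = dplus_i(p, k)
            rows.append(r), cols.append(i_plus), vals.append(1.0)
            rows.append(r), cols.append(i_plus + 1), vals.append(-1.0)
            for b in range(B):
                coef = (volumes[b] / 100.0) * (comp[b, k] - targets[k])
                rows.append(r), cols.append(xi(b, p)), vals.append(-coef)
            lb.append(0.0), ub.append(0.0)
            r += 1

    A = sparse.csr_array((vals, (rows, cols)), shape=(r, n_var))
    constraints = LinearConstraint(A, np.array(lb), np.array(ub))

    c = np.zeros(n_var)
    half = {"protein": 0.0, "energy": 0.0}
    if uncertainty is not None:
        half = {"protein": uncertainty.e_protein, "energy": uncertainty.e_energy}
    for p in range(P):
        for k, nut in enumerate(NUTRIENTS):
            i_plus = dplus_i(p, k)
            c[i_plus] = 1.0 / norms[nut]
            c[i_plus + 1] = 1.0 / norms[nut]
    for b in range(B):
        wc_term = sum((volumes[b] / 100.0) * half[nut] / norms[nut] for nut in NUTRIENTS)
        for p in range(P):
            c[xi(b, p)] = -config.priority_weight * urgency[b] + wc_term

    integrality = np.zeros(n_var)
    integrality[: n_x + n_y] = 1
    var_ub = np.full(n_var, np.inf)
    var_ub[: n_x + n_y] = 1.0
    # Pools are interchangeable, which makes the search tree massively
    # symmetric.  Relabelling pools by their minimal member bottle index
    # shows some optimum always has bottle b only in pools 0..b, so fixing
    # x[b,p] = 0 for p > b is a valid symmetry break.
    for b in range(min(B, P)):
        for p in range(b + 1, P):
            var_ub[xi(b, p)] = 0.0
    bnds = Bounds(np.zeros(n_var), var_ub)

    return MilpModel(
        bottles=list(bottles),
        config=config,
        contents=contents,
        urgency=urgency,
        donors=donors,
        constraints=constraints,
        objective=c,
        integrality=integrality,
        bounds=bnds,
        n_x=n_x,
        n_y=n_y,
    )


@dataclass
class PoolAssignment:
    """An evaluated bottle-to-pool assignment.

    ``dev_protein`` / ``dev_energy`` are the exact normalised deviations
    |c_pool - T_n| / T_n per pool; ``objective_total`` is their sum and
    ``linear_objective`` the fixed-reference-volume normalisation the MILP
    minimises (the two differ by at most vmax/vmin).
    """

    pools: list[PoolRecord]
    members: dict[str, list[BottleRecord]] = field(repr=False, default_factory=dict)
    dev_protein: dict[str, float] = field(default_factory=dict)
    dev_energy: dict[str, float] = field(default_factory=dict)
    objective_total: float = 0.0
    objective_per_pool: float = 0.0
    linear_objective: float = 0.0
    status: str = "evaluated"
    gap: float | None = None
    infeasible_reason: str | None = None

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def is_feasible(self) -> bool:
        return self.status not in ("infeasible",)

    def bottle_to_pool(self) -> dict[str, str]:
        return {b.bottle_id: pid for pid, bs in self.members.items() for b in bs}

    def mean_donors_per_pool(self) -> float:
        if not self.pools:
            return float("nan")
        return float(np.mean([len(p.donor_ids) for p in self.pools]))


def evaluate_assignment(
    assignment,
    contents: pd.DataFrame | None,
    config: PoolingConfig,
) -> PoolAssignment:
    """Recompute pool compositions and deviations for a fixed assignment.

    ``assignment`` is either a ``{pool_id: [BottleRecord, ...]}`` mapping or
    an existing :class:`PoolAssignment` (its membership is reused).
    ``contents`` maps bottle_id to composition columns (``protein``/``energy``
    or ``pred_protein``/``pred_energy``); ``None`` uses each bottle's own
    composition.  Evaluation is independent of any solver state.
    """
    if isinstance(assignment, PoolAssignment):
        members = assignment.members
    else:
        members = dict(assignment)

    lookup = None
    if contents is not None:
        df = contents.rename(
            columns={"pred_protein": "protein", "pred_energy": "energy",
                     "crude_protein": "protein"}
        )
        lookup = df.set_index("bottle_id")[["protein", "energy"]]

    pools: list[PoolRecord] = []
    dev_p: dict[str, float] = {}
    dev_e: dict[str, float] = {}
    norms = _deviation_norms(config)
    linear_total = 0.0
    for pool_id in sorted(members):
        bottles = members[pool_id]
        if lookup is not None:
            comp_bottles = []
            for b in bottles:
                if b.bottle_id not in lookup.index:
                    raise ReferentialError(
                        f"assignment references bottle {b.bottle_id!r} absent from contents"
                    )
                comp_bottles.append(
                    b.with_composition(
                        float(lookup.at[b.bottle_id, "protein"]),
                        float(lookup.at[b.bottle_id, "energy"]),
                    )
                )
        else:
            comp_bottles = bottles
        pool = PoolRecord.from_bottles(pool_id, comp_bottles)
        pools.append(pool)
        dev_p[pool_id] = abs(pool.crude_protein - config.target_protein) / config.target_protein
        dev_e[pool_id] = abs(pool.energy - config.target_energy) / config.target_energy
        for nut, c_pool, target in (
            ("protein", pool.crude_protein, config.target_protein),
            ("energy", pool.energy, config.target_energy),
        ):
            mass_dev = abs(c_pool - target) * pool.total_volume_ml / 100.0
            linear_total += mass_dev / norms[nut]

    total = sum(dev_p.values()) + sum(dev_e.values())
    return PoolAssignment(
        pools=pools,
        members=members,
        dev_protein=dev_p,
        dev_energy=dev_e,
        objective_total=total,
        objective_per_pool=total / len(pools) if pools else float("nan"),
        linear_objective=linear_total,
    )


def _audit_assignment(members: dict[str, list[BottleRecord]], config: PoolingConfig) -> None:
    """Independent feasibility audit; raises on any violated requirement."""
    seen: set[str] = set()
    for pool_id, bottles in members.items():
        vol = sum(b.volume_ml for b in bottles)
        if not (config.vmin_ml - 1e-6 <= vol <= config.vmax_ml + 1e-6):
            raise ValidationError(
                f"audit: pool {pool_id} volume {vol:.1f} outside "
                f"[{config.vmin_ml}, {config.vmax_ml}]"
            )
        donors = {b.donor_id for b in bottles}
        if not (config.min_donors <= len(donors) <= config.max_donors):
            raise ValidationError(
                f"audit: pool {pool_id} uses {len(donors)} donors, outside "
                f"[{config.min_donors}, {config.max_donors}]"
            )
        for b in bottles:
            if b.bottle_id in seen:
                raise ValidationError(f"audit: bottle {b.bottle_id} assigned twice")
            seen.add(b.bottle_id)


def _diagnose_infeasibility(model: MilpModel, time_limit: float) -> str:
    """Identify the first violated requirement class: volume or donor-count.

    Re-solves with the donor-count window removed; if that relaxation is
    feasible the donor requirements are the blocker, otherwise the volume
    window is.
    """
    cfg = model.config
    relaxed_cfg = cfg.replace(min_donors=1, max_donors=10**6)
    # reuse the original contents (predictions already folded in)
    as_predictions = model.contents.rename(
        columns={"protein": "pred_protein", "energy": "pred_energy"}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # volume warning already issued upstream
        relaxed = build_model(model.bottles, relaxed_cfg, predictions=as_predictions)
    res = milp(
        c=np.zeros_like(relaxed.objective),
        constraints=relaxed.constraints,
        integrality=relaxed.integrality,
        bounds=relaxed.bounds,
        options={"time_limit": time_limit, "presolve": True},
    )
    return "donor-count" if res.status == 0 else "volume"


def solve(
    model: MilpModel,
    time_limit: float = 300.0,
    gap: float = 1e-6,
    raise_on_infeasible: bool = False,
) -> PoolAssignment:
    """Solve the pooling MILP with HiGHS branch-and-bound.

    The returned assignment is independently re-audited against every
    constraint, and its deviations are recomputed from the model's contents
    table.  On infeasibility the violated requirement class (volume vs
    donor-count) is identified via elastic diagnosis; on a time limit the
    best incumbent is returned with ``status="time_limit"``.
    """
    res = milp(
        c=model.objective,
        constraints=model.constraints,
        integrality=model.integrality,
        bounds=model.bounds,
        options={"time_limit": time_limit, "mip_rel_gap": gap, "presolve": True},
    )
    infeasible = res.status == 2 or (res.status != 0 and res.x is None)
    if infeasible:
        reason = _diagnose_infeasibility(model, time_limit)
        if raise_on_infeasible:
            raise InfeasibleError(f"pooling model infeasible ({reason})", reason=reason)
        return PoolAssignment(
            pools=[], members={}, status="infeasible", infeasible_reason=reason
        )

    x = res.x[: model.n_x]
    P = model.config.n_pools
    members: dict[str, list[BottleRecord]] = {}
    for b, bottle in enumerate(model.bottles):
        for p in range(P):
            if x[b * P + p] > 0.5:
                members.setdefault(f"P{p:03d}", []).append(bottle)
    _audit_assignment(members, model.config)

    assignment = evaluate_assignment(members, model.contents, model.config)
    assignment.status = "optimal" if res.status == 0 else "time_limit"
    assignment.gap = float(res.mip_gap) if res.mip_gap is not None else None
    return assignment


def suggest_n_pools(bottles: list[BottleRecord], config: PoolingConfig) -> int:
    """Default pool count for an inventory: floor(total volume / vmax)."""
    return int(sum(b.volume_ml for b in bottles) // config.vmax_ml)


def brute_force_oracle(
    bottles: list[BottleRecord],
    config: PoolingConfig,
    contents: pd.DataFrame | None = None,
) -> tuple[float | None, dict[str, list[BottleRecord]] | None]:
    """Exhaustively enumerate all feasible assignments of a small instance.

    Returns ``(objective, members)`` for the minimal deviation objective
    (priority term excluded; same fixed-reference normalisation as the MILP)
    or ``(None, None)`` when no feasible assignment exists.  Refuses
    instances above 14 bottles or 2 pools.
    """
    B, P = len(bottles), config.n_pools
    if B > 14 or P > 2:
        raise EnumerationBoundError(
            f"oracle bound exceeded: {B} bottles / {P} pools (max 14 / 2)"
        )
    table = contents_table(bottles, None) if contents is None else contents
    comp = table[["protein", "energy"]].to_numpy()
    volumes = np.array([b.volume_ml for b in bottles])
    donors = [b.donor_id for b in bottles]
    targets = np.array([config.target_protein, config.target_energy])
    norms_arr = np.array(
        [_deviation_norms(config)["protein"], _deviation_norms(config)["energy"]]
    )

    feasible: list[tuple[int, float]] = []  # (bitmask, objective contribution)
    for mask in range(1, 1 << B):
        idx = [b for b in range(B) if mask >> b & 1]
        vol = volumes[idx].sum()
        if not (config.vmin_ml <= vol <= config.vmax_ml):
            continue
        ndon = len({donors[b] for b in idx})
        if not (config.min_donors <= ndon <= config.max_donors):
            continue
        mass = (volumes[idx, None] / 100.0 * comp[idx]).sum(axis=0)
        dev = np.abs(mass - targets * vol / 100.0) / norms_arr
        feasible.append((mask, float(dev.sum())))

    best_obj, best_masks = None, None
    if P == 1:
        for mask, obj in feasible:
            if best_obj is None or obj < best_obj:
                best_obj, best_masks = obj, (mask,)
    else:
        for i, (m1, o1) in enumerate(feasible):
            for m2, o2 in feasible:
                if m1 & m2 or m2 <= m1:  # disjoint, unordered pair
                    continue
                obj = o1 + o2
                if best_obj is None or obj < best_obj:
                    best_obj, best_masks = obj, (m1, m2)
    if best_obj is None:
        return None, None
    members = {
        f"P{p:03d}": [bottles[b] for b in range(B) if best_masks[p] >> b & 1]
        for p in range(len(best_masks))
    }
    return best_obj, members
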