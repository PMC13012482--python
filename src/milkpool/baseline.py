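"""Current-practice simulation and strategy comparison.

The bank's current practice pools milk from a *single* donor: bottles from
one donor, in expression-date order, accumulate until the ~2-L minimum is
reached.  The alternative strategy solves the multi-donor pooling MILP on
predicted compositions.  Both strategies are replayed over a rolling freezer
timeline — at each pooling date a strategy sees only bottles that have
arrived, have not expired, and have not been consumed — and are then scored
against the *true* (synthetic) compositions, so the comparison measures
realised nutritional stability, not predicted stability.  Waste (volume that
expires unconsumed) and the remaining shelf life of each pool (its earliest
member expiry minus the pooling date) are tracked alongside.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .optimise import build_model, solve, suggest_n_pools
from .records import BottleRecord, PoolingConfig, PoolRecord
from .synthetic import FreezerTimeline

__all__ = [
    "ScenarioResult",
    "simulate_current_practice",
    "run_rolling_horizon",
    "compare_strategies",
    "weekly_dates",
    "inventory_hash",
]

STRATEGIES = ("single_donor", "optimised")


def inventory_hash(bottles: list[BottleRecord]) -> str:
    """Stable fingerprint of an inventory (ids, volumes, arrival dates)."""
    h = hashlib.sha256()
    for b in sorted(bottles, key=lambda x: x.bottle_id):
        h.update(f"{b.bottle_id}|{b.volume_ml:.6f}|{b.arrival_date.isoformat()};".encode())
    return h.hexdigest()[:16]


def weekly_dates(start: date, end: date) -> list[date]:
    """Pooling cadence default: one pooling session per week."""
    out, d = [], start
    while d <= end:
        out.append(d)
        d += timedelta(days=7)
    return out


@dataclass
class ScenarioResult:
    """Outcome of replaying one strategy over an inventory timeline."""

    strategy: str
    pools: list[PoolRecord]
    created_on: dict[str, date]
    dev_protein: dict[str, float]
    dev_energy: dict[str, float]
    avg_total_abs_deviation: float
    expired_unused_volume: float
    leftover_volume: float
    consumed_volume: float
    mean_remaining_shelf_life: float
    inventory_fingerprint: str
    per_pool_deviation: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_pools(self) -> int:
        return len(self.pools)


def simulate_current_practice(
    bottles: list[BottleRecord],
    config: PoolingConfig,
    *,
    skip_overshoot: bool = False,
    start_index: int = 0,
) -> list[tuple[PoolRecord, list[BottleRecord]]]:
    """Greedy single-donor pooling of a bottle set.

    Per donor, bottles in expression-date order accumulate; a pool closes at
    the first bottle bringing the cumulative volume to at least ``vmin_ml``.
    Sub-``vmin`` tails remain unpooled.  With ``skip_overshoot`` a closing
    bottle that would push the pool past ``vmax_ml`` is skipped instead
    (stricter variant of the practice).
    """
    by_donor: dict[str, list[BottleRecord]] = {}
    for b in bottles:
        by_donor.setdefault(b.donor_id, []).append(b)

    out: list[tuple[PoolRecord, list[BottleRecord]]] = []
    k = start_index
    for donor_id in sorted(by_donor):
        batch: list[BottleRecord] = []
        vol = 0.0
        for b in sorted(by_donor[donor_id], key=lambda x: (x.expression_date, x.bottle_id)):
            if skip_overshoot and vol + b.volume_ml > config.vmax_ml:
                continue
            batch.append(b)
            vol += b.volume_ml
            if vol >= config.vmin_ml:
                pool = PoolRecord.from_bottles(f"S{k:04d}", batch)
                out.append((pool, batch))
                k += 1
                batch, vol = [], 0.0
    return out


def _deviations(pool: PoolRecord, config: PoolingConfig) -> tuple[float, float]:
    dev_p = abs(pool.crude_protein - config.target_protein) / config.target_protein
    dev_e = abs(pool.energy - config.target_energy) / config.target_energy
    return dev_p, dev_e


def run_rolling_horizon(
    inventory,
    strategy: str,
    config: PoolingConfig,
    pooling_dates: list[date],
    predictions: pd.DataFrame | None = None,
    *,
    time_limit: float = 60.0,
    gap: float = 1e-4,
) -> ScenarioResult:
    """Replay a pooling strategy over the freezer timeline.

    ``inventory`` is a bottle list or a :class:`FreezerTimeline` (a fresh
    timeline is always built, so the caller's state is untouched).  At each
    pooling date the strategy sees only arrived, unexpired, unconsumed
    bottles.  The ``optimised`` strategy needs a bottle-level ``predictions``
    table and creates ``floor(available volume / vmax)`` pools per date
    (fewer when donor availability forces it).  Realised pool compositions
    and deviations always come from the bottles' own (true) compositions.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    bottles = inventory.bottles if isinstance(inventory, FreezerTimeline) else list(inventory)
    if strategy == "optimised" and predictions is None:
        raise ValidationError("the optimised strategy needs a predictions table")
    timeline = FreezerTimeline(bottles)
    fingerprint = inventory_hash(bottles)

    pools: list[PoolRecord] = []
    created_on: dict[str, date] = {}
    dev_p: dict[str, float] = {}
    dev_e: dict[str, float] = {}

    for when in sorted(pooling_dates):
        available = timeline.available(when)
        if not available:
            continue
        if strategy == "single_donor":
            formed = simulate_current_practice(
                available, config, start_index=len(pools)
            )
            for pool, members in formed:
                timeline.consume([b.bottle_id for b in members], when)
                pools.append(pool)
                created_on[pool.pool_id] = when
                dev_p[pool.pool_id], dev_e[pool.pool_id] = _deviations(pool, config)
        else:
            n = min(
                suggest_n_pools(available, config),
                # each pool needs min_donors distinct donors, but donors may
                # serve several pools; zero distinct-donor shortfall guard
                10**9 if len({b.donor_id for b in available}) >= config.min_donors else 0,
            )
            while n >= 1:
                cfg = config.replace(n_pools=n)
                model = build_model(available, cfg, predictions=predictions, asof=when)
                assignment = solve(model, time_limit=time_limit, gap=gap)
                if assignment.is_feasible:
                    for pool_id in sorted(assignment.members):
                        members = assignment.members[pool_id]
                        timeline.consume([b.bottle_id for b in members], when)
                        pool = PoolRecord.from_bottles(f"O{len(pools):04d}", members)
                        pools.append(pool)
                        created_on[pool.pool_id] = when
                        dev_p[pool.pool_id], dev_e[pool.pool_id] = _deviations(pool, config)
                    break
                n -= 1

    end = max(pooling_dates)
    totals = [dev_p[p.pool_id] + dev_e[p.pool_id] for p in pools]
    shelf = [
        (p.shelf_life_date - created_on[p.pool_id]).days for p in pools
    ]
    per_pool = pd.DataFrame(
        {
            "pool_id": [p.pool_id for p in pools],
            "n_donors": [len(p.donor_ids) for p in pools],
            "volume_ml": [p.total_volume_ml for p in pools],
            "dev_protein": [dev_p[p.pool_id] for p in pools],
            "dev_energy": [dev_e[p.pool_id] for p in pools],
            "total_deviation": totals,
            "remaining_shelf_life_days": shelf,
        }
    )
    return ScenarioResult(
        strategy=strategy,
        pools=pools,
        created_on=created_on,
        dev_protein=dev_p,
        dev_energy=dev_e,
        avg_total_abs_deviation=float(np.mean(totals)) if totals else float("nan"),
        expired_unused_volume=timeline.expired_unused_volume(end),
        leftover_volume=timeline.leftover_volume(end),
        consumed_volume=timeline.consumed_volume(),
        mean_remaining_shelf_life=float(np.mean(shelf)) if shelf else float("nan"),
        inventory_fingerprint=fingerprint,
        per_pool_deviation=per_pool,
    )


def compare_strategies(a: ScenarioResult, b: ScenarioResult) -> dict:
    """Compare two strategy runs on the same inventory.

    ``improvement_percent`` is (dev_a - dev_b) / dev_a * 100, i.e. how much
    strategy ``b`` reduces the average total absolute deviation relative to
    ``a`` (positive when ``b`` is more stable).
    """
    if a.inventory_fingerprint != b.inventory_fingerprint:
        raise ValidationError(
            "cannot compare strategies run on different inventories "
            f"({a.inventory_fingerprint} vs {b.inventory_fingerprint})"
        )
    dev_a, dev_b = a.avg_total_abs_deviation, b.avg_total_abs_deviation
    improvement = 100.0 * (dev_a - dev_b) / dev_a if dev_a else 0.0
    return {
        "strategy_a": a.strategy,
        "strategy_b": b.strategy,
        "avg_total_abs_deviation_a": dev_a,
        "avg_total_abs_deviation_b": dev_b,
        "improvement_percent": improvement,
        "n_pools_a": a.n_pools,
        "n_pools_b": b.n_pools,
        "expired_unused_volume_a": a.expired_unused_volume,
        "expired_unused_volume_b": b.expired_unused_volume,
        "mean_remaining_shelf_life_a": a.mean_remaining_shelf_life,
        "mean_remaining_shelf_life_b": b.mean_remaining_shelf_life,
    }
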