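"""Shared fixtures: cohorts, training pools, fitted models, instance makers.

Expensive artefacts (the full default cohort and the tuned model suite) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from milkpool import (
    BottleRecord,
    GeneratorParams,
    PoolingConfig,
    form_single_donor_training_pools,
    generate_cohort,
    train_suite,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale default cohort (~480 donors, ~2.1k training pools)."""
    return generate_cohort(GeneratorParams())


@pytest.fixture(scope="session")
def default_pools(default_cohort):
    return form_single_donor_training_pools(
        default_cohort.bottles, default_cohort.donors, rng=0
    )


@pytest.fixture(scope="session")
def trained_suites(default_pools):
    """Fitted model suites and metric reports for both nutrients."""
    out = {}
    for nutrient in ("protein", "energy"):
        models, report = train_suite(default_pools, nutrient, split_seed=0)
        out[nutrient] = (models, report)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort for rolling-horizon scenarios (fresh donors)."""
    params = GeneratorParams(
        n_donors=12,
        seed=11,
        delivery_spread_days=30,
        donation_start_range=(30, 90),
        donation_duration_range=(6, 12),
    )
    return generate_cohort(params)


def make_random_instance(
    seed: int,
    n_bottles: int = 10,
    n_donors: int = 4,
    volume_range: tuple[float, float] = (300.0, 700.0),
) -> list[BottleRecord]:
    """Small random pooling instance with known composition.

    Volumes are drawn large enough that a handful of bottles can hit the
    2.00-2.05 L window, which keeps random instances frequently feasible.
    """
    rng = np.random.default_rng(seed)
    bottles = []
    for i in range(n_bottles):
        bottles.append(
            BottleRecord(
                bottle_id=f"b{seed}_{i}",
                donor_id=f"d{int(rng.integers(n_donors))}",
                expression_date=date(2023, 1, 1),
                arrival_date=date(2023, 1, 2) + timedelta(days=int(rng.integers(0, 20))),
                volume_ml=float(rng.uniform(*volume_range)),
                days_postpartum=int(rng.integers(30, 200)),
                crude_protein=float(rng.uniform(0.7, 1.3)),
                energy=float(rng.uniform(55.0, 85.0)),
            )
        )
    return bottles


@pytest.fixture
def zero_deviation_bottles():
    """Four single-bottle donors predicted exactly at the targets; one pool
    of 2020 mL and 4 donors is the obvious optimum with zero deviation."""
    return [
        BottleRecord(
            bottle_id=f"Z{i}",
            donor_id=f"DZ{i}",
            expression_date=date(2023, 1, 1),
            arrival_date=date(2023, 1, 5),
            volume_ml=505.0,
            days_postpartum=30,
            crude_protein=1.0,
            energy=70.0,
        )
        for i in range(4)
    ]


@pytest.fixture
def config():
    return PoolingConfig()
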