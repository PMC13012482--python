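"""Synthetic donor cohort generator.

Emulates the operating conditions of a national human milk bank: ~480
accepted donors whose frozen donations (50-250 mL bottles) are combined into
roughly 2-litre single-donor pools (~2236 of them), each pool measured once
on a mid-infrared human milk analyser.  The generator produces donors with
correlated covariates, a dated donation timeline per donor, and a bottle-level
ground-truth composition built from three parts:

* fixed covariate effects (days postpartum, BMI, age, preterm delivery,
  vegetarian diet, expressed volume) whose sizes are calibrated so the
  pool-level Pearson correlations land on the exploratory-analysis targets
  (protein: days postpartum -0.20, BMI -0.10, age -0.10, preterm +0.06,
  vegetarian +0.05, volume ~0; energy: days postpartum +0.17, volume -0.15,
  BMI +0.05, age +0.17; protein-energy cross +0.16);
* correlated per-donor random intercepts, the within-donor consistency that
  makes single-donor pools nutritionally variable between donors; and
* bottle-level residual noise plus analyser measurement noise
  (0.10 g/100 mL for crude protein) added once per measured pool.

Identities enforced for every bottle: crude protein = 1.2 x true protein
(non-protein nitrogen allowance) and energy = 4*protein + 9*fat + 4*carb
(Atwater factors); fat is derived from energy, protein and carbohydrate so
the identity holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .records import BottleRecord, DonorRecord, PoolingConfig

__all__ = [
    "GeneratorParams",
    "SyntheticCohort",
    "generate_cohort",
    "form_single_donor_training_pools",
    "simulate_arrivals",
    "FreezerTimeline",
    "TRAINING_FEATURES",
]

#: fixed feature order used by the prediction models
TRAINING_FEATURES = ["days_postpartum", "avg_volume", "bmi", "preterm", "age", "vegetarian"]

# centring constants for the linear effects (approximate cohort means)
_DPP_CENTER = 155.0    # days postpartum
_VOL_CENTER = 170.0    # mL per expression
_BMI_CENTER = 24.0
_AGE_CENTER = 32.0


@dataclass
class GeneratorParams:
    """Knobs of the synthetic cohort; defaults are the emulated bank's conditions.

    Effect coefficients are per unit of the (centred) covariate and were
    calibrated once so the pool-level correlation table at ~2236 pools
    recovers the target coefficients within +-0.05.  ``sigma_donor_*`` are
    the SDs of the correlated donor random intercepts; ``sigma_bottle_*``
    the bottle-level residual SDs; ``noise_*`` the analyser measurement
    noise added to each measured pool.
    """

    n_donors: int = 480
    seed: int = 0
    base_date: date = date(2023, 1, 1)

    # donor covariates
    age_mean: float = 32.0
    age_sd: float = 4.0
    age_bounds: tuple[float, float] = (18.0, 45.0)
    bmi_mean: float = 24.0
    bmi_sd: float = 3.5
    bmi_bounds: tuple[float, float] = (17.0, 40.0)
    p_vegetarian: float = 0.12      # ~269 of 2236 pools
    p_preterm: float = 0.25         # ~566 of 2236 pools

    # donation timeline: daily expression sessions inside a window of
    # lactation, several bottles per day, delivered to the bank in batches
    delivery_spread_days: int = 150
    donation_start_range: tuple[int, int] = (30, 240)   # days postpartum
    donation_duration_range: tuple[int, int] = (11, 30)  # days
    bottles_per_day_range: tuple[int, int] = (2, 4)
    donor_volume_range: tuple[float, float] = (100.0, 240.0)  # mL, donor mean
    bottle_volume_sd: float = 20.0
    volume_bounds: tuple[float, float] = (50.0, 250.0)
    arrival_delay_range: tuple[int, int] = (2, 10)       # days after expression

    # crude protein effects, g/100 mL per covariate unit
    beta_protein_dpp: float = -6.6e-4
    beta_protein_bmi: float = -0.0059
    beta_protein_age: float = -0.0050
    beta_protein_preterm: float = 0.0285
    beta_protein_veg: float = 0.0315
    protein_base: float = 1.0

    # energy effects, kcal/100 mL per covariate unit
    beta_energy_dpp: float = 0.0200
    beta_energy_vol: float = -0.0225
    beta_energy_bmi: float = 0.1050
    beta_energy_age: float = 0.3000
    energy_base: float = 70.0

    # random structure
    sigma_donor_protein: float = 0.15
    sigma_donor_energy: float = 6.0
    donor_effect_corr: float = 0.36   # couples donor protein/energy intercepts
    sigma_bottle_protein: float = 0.25
    sigma_bottle_energy: float = 9.3
    noise_protein: float = 0.10       # analyser SD, g/100 mL
    noise_energy: float = 1.5         # analyser SD, kcal/100 mL

    # composition accounting
    carb_mean: float = 7.0
    carb_sd: float = 0.25
    protein_floor: float = 0.4
    energy_floor: float = 45.0
    fat_floor: float = 0.5

    def __post_init__(self):
        if self.n_donors <= 0:
            raise ValidationError(f"n_donors must be positive, got {self.n_donors}")
        for name in ("sigma_donor_protein", "sigma_donor_energy",
                     "sigma_bottle_protein", "sigma_bottle_energy",
                     "noise_protein", "noise_energy", "carb_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("p_vegetarian", "p_preterm"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.volume_bounds
        if not (50.0 <= lo < hi <= 250.0):
            raise ValidationError(
                f"volume_bounds must lie within [50, 250] mL, got {self.volume_bounds}"
            )
        if not -1 < self.donor_effect_corr < 1:
            raise ValidationError("donor_effect_corr must be in (-1, 1)")


@dataclass
class SyntheticCohort:
    """Generated cohort: donors, bottles carrying true composition, and the
    full per-bottle truth table (true protein, fat, carbohydrate, crude
    protein, energy)."""

    donors: list[DonorRecord]
    bottles: list[BottleRecord]
    truth: pd.DataFrame
    params: GeneratorParams = field(repr=False, default=None)

    @property
    def donor_map(self) -> dict[str, DonorRecord]:
        return {d.donor_id: d for d in self.donors}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Resampling truncation; keeps the distribution shape inside bounds."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(params: GeneratorParams | None = None) -> SyntheticCohort:
    """Generate a dated donor cohort with ground-truth bottle composition.

    Deterministic given ``params.seed``.  Every bottle's ``crude_protein``
    and ``energy`` hold the *true* (noise-free) values; measurement noise is
    added only when pools are measured by
    :func:`form_single_donor_training_pools`.
    """
    p = params or GeneratorParams()
    rng = np.random.default_rng(p.seed)

    n = p.n_donors
    age = _truncated_normal(rng, p.age_mean, p.age_sd, *p.age_bounds, size=n)
    bmi = _truncated_normal(rng, p.bmi_mean, p.bmi_sd, *p.bmi_bounds, size=n)
    vegetarian = (rng.random(n) < p.p_vegetarian).astype(int)
    preterm = (rng.random(n) < p.p_preterm).astype(int)
    delivery_offset = rng.integers(0, p.delivery_spread_days + 1, size=n)

    start = rng.integers(p.donation_start_range[0], p.donation_start_range[1] + 1, size=n)
    duration = rng.integers(
        p.donation_duration_range[0], p.donation_duration_range[1] + 1, size=n
    )
    mean_vol = rng.uniform(*p.donor_volume_range, size=n)

    # correlated donor intercepts (protein, energy)
    rho = p.donor_effect_corr
    cov = np.array(
        [
            [p.sigma_donor_protein**2, rho * p.sigma_donor_protein * p.sigma_donor_energy],
            [rho * p.sigma_donor_protein * p.sigma_donor_energy, p.sigma_donor_energy**2],
        ]
    )
    donor_effects = rng.multivariate_normal(np.zeros(2), cov, size=n)
    # In moderate cohorts a chance alignment between donor intercepts and
    # donor-level covariates confounds the calibrated correlation structure
    # (sampling SE ~ 1/sqrt(n_donors), much larger than 1/sqrt(n_pools)).
    # Project the intercepts off the donor-level design so the fixed effects
    # carry exactly the intended associations; rescale to the target SDs.
    if n >= 30:
        design = np.column_stack(
            [np.ones(n), age, bmi, vegetarian, preterm, start, mean_vol]
        )
        beta_hat, *_ = np.linalg.lstsq(design, donor_effects, rcond=None)
        donor_effects = donor_effects - design @ beta_hat
        for col, sigma in enumerate((p.sigma_donor_protein, p.sigma_donor_energy)):
            s = donor_effects[:, col].std()
            if s > 0:
                donor_effects[:, col] *= sigma / s

    donors: list[DonorRecord] = []
    bottles: list[BottleRecord] = []
    truth_rows: list[dict] = []

    for i in range(n):
        donor_id = f"D{i:04d}"
        delivery = p.base_date + timedelta(days=int(delivery_offset[i]))
        donors.append(
            DonorRecord(
                donor_id=donor_id,
                age=float(age[i]),
                bmi=float(bmi[i]),
                vegetarian=int(vegetarian[i]),
                preterm=int(preterm[i]),
                delivery_date=delivery,
            )
        )
        u_protein, u_energy = donor_effects[i]

        j = 0
        for day in range(int(start[i]), int(start[i] + duration[i])):
            n_bottles = int(
                rng.integers(p.bottles_per_day_range[0], p.bottles_per_day_range[1] + 1)
            )
            delay = int(rng.integers(p.arrival_delay_range[0], p.arrival_delay_range[1] + 1))
            for _ in range(n_bottles):
                volume = float(
                    np.clip(rng.normal(mean_vol[i], p.bottle_volume_sd), *p.volume_bounds)
                )
                protein = (
                    p.protein_base
                    + p.beta_protein_dpp * (day - _DPP_CENTER)
                    + p.beta_protein_bmi * (bmi[i] - _BMI_CENTER)
                    + p.beta_protein_age * (age[i] - _AGE_CENTER)
                    + p.beta_protein_preterm * preterm[i]
                    + p.beta_protein_veg * vegetarian[i]
                    + u_protein
                    + rng.normal(0.0, p.sigma_bottle_protein)
                )
                energy = (
                    p.energy_base
                    + p.beta_energy_dpp * (day - _DPP_CENTER)
                    + p.beta_energy_vol * (volume - _VOL_CENTER)
                    + p.beta_energy_bmi * (bmi[i] - _BMI_CENTER)
                    + p.beta_energy_age * (age[i] - _AGE_CENTER)
                    + u_energy
                    + rng.normal(0.0, p.sigma_bottle_energy)
                )
                carb = float(np.clip(rng.normal(p.carb_mean, p.carb_sd), 6.0, 8.0))
                protein = max(protein, p.protein_floor)
                # fat is the energy residual after protein and carbohydrate;
                # keep it physical by flooring energy accordingly
                energy = max(energy, p.energy_floor, 4 * protein + 4 * carb + 9 * p.fat_floor)
                fat = (energy - 4 * protein - 4 * carb) / 9.0

                expression = delivery + timedelta(days=day)
                bottle_id = f"{donor_id}-B{j:03d}"
                j += 1
                bottles.append(
                    BottleRecord(
                        bottle_id=bottle_id,
                        donor_id=donor_id,
                        expression_date=expression,
                        arrival_date=expression + timedelta(days=delay),
                        volume_ml=volume,
                        days_postpartum=day,
                        crude_protein=protein,
                        energy=energy,
                    )
                )
                truth_rows.append(
                    {
                        "bottle_id": bottle_id,
                        "true_protein": protein / 1.2,
                        "fat": fat,
                        "carbohydrate": carb,
                        "crude_protein": protein,
                        "energy": energy,
                    }
                )

    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(donors=donors, bottles=bottles, truth=truth, params=p)


def form_single_donor_training_pools(
    bottles: list[BottleRecord],
    donors: list[DonorRecord],
    config: PoolingConfig | None = None,
    *,
    noise_protein: float = 0.10,
    noise_energy: float = 1.5,
    max_span_days: int = 7,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Form single-donor ~2-L training pools and measure them.

    Mirrors current milk-bank practice: per donor, bottles in expression-date
    order accumulate greedily into a pool that closes at the first bottle
    reaching ``config.vmin_ml``; only bottles pumped on adjacent dates are
    pooled together (within-pool days-postpartum span <= ``max_span_days``),
    so an accumulating pool is abandoned and restarted when the next bottle
    would stretch it past that span.  Each closed pool gets one analyser
    measurement: the volume-weighted true composition plus Gaussian
    measurement noise.

    Returns one row per pool with the measured composition and the
    pool-averaged features used for model training (days postpartum, volume
    per expression) joined with the donor covariates.
    """
    config = config or PoolingConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    donor_map = {d.donor_id: d for d in donors}

    by_donor: dict[str, list[BottleRecord]] = {}
    for b in bottles:
        if b.crude_protein is None or b.energy is None:
            raise ValidationError(
                f"bottle {b.bottle_id}: training pools need ground-truth composition"
            )
        by_donor.setdefault(b.donor_id, []).append(b)

    rows: list[dict] = []
    k = 0
    for donor_id in sorted(by_donor):
        donor = donor_map.get(donor_id)
        if donor is None:
            raise ValidationError(f"bottle references unknown donor {donor_id!r}")
        batch: list[BottleRecord] = []
        for b in sorted(by_donor[donor_id], key=lambda x: (x.expression_date, x.bottle_id)):
            if batch:
                span = (b.expression_date - batch[0].expression_date).days
                if span > max_span_days:
                    batch = []  # stale accumulation: restart from this bottle
            batch.append(b)
            vol = sum(x.volume_ml for x in batch)
            if vol >= config.vmin_ml:
                w = np.array([x.volume_ml for x in batch])
                protein_true = float(
                    np.dot(w, [x.crude_protein for x in batch]) / w.sum()
                )
                energy_true = float(np.dot(w, [x.energy for x in batch]) / w.sum())
                measured_protein = max(
                    protein_true + rng.normal(0.0, noise_protein), 0.05
                )
                measured_energy = max(energy_true + rng.normal(0.0, noise_energy), 1.0)
                rows.append(
                    {
                        "pool_id": f"TP{k:05d}",
                        "donor_id": donor_id,
                        "bottle_ids": ";".join(x.bottle_id for x in batch),
                        "n_bottles": len(batch),
                        "volume_ml": vol,
                        "days_postpartum": float(
                            np.mean([x.days_postpartum for x in batch])
                        ),
                        "avg_volume": float(np.mean(w)),
                        "bmi": donor.bmi,
                        "preterm": donor.preterm,
                        "age": donor.age,
                        "vegetarian": donor.vegetarian,
                        "crude_protein": measured_protein,
                        "energy": measured_energy,
                        "true_protein_pool": protein_true,
                        "true_energy_pool": energy_true,
                    }
                )
                k += 1
                batch = []
    return pd.DataFrame(rows)


class FreezerTimeline:
    """Availability timeline of frozen bottles.

    A bottle is available on a query date when it has arrived, has not yet
    expired (half-open interval ``arrival <= date < expiry``), and has not
    been consumed on or before that date.
    """

    def __init__(self, bottles: list[BottleRecord]):
        self._bottles = sorted(bottles, key=lambda b: (b.arrival_date, b.bottle_id))
        self._by_id = {b.bottle_id: b for b in self._bottles}
        self._consumed_on: dict[str, date] = {}

    def __len__(self) -> int:
        return len(self._bottles)

    @property
    def bottles(self) -> list[BottleRecord]:
        return list(self._bottles)

    def bottle(self, bottle_id: str) -> BottleRecord:
        return self._by_id[bottle_id]

    def available(self, on: date) -> list[BottleRecord]:
        out = []
        for b in self._bottles:
            if not (b.arrival_date <= on < b.expiry_date):
                continue
            consumed = self._consumed_on.get(b.bottle_id)
            if consumed is not None and consumed <= on:
                continue
            out.append(b)
        return out

    def consume(self, bottle_ids, on: date) -> None:
        for bid in bottle_ids:
            if bid not in self._by_id:
                raise ValidationError(f"cannot consume unknown bottle {bid!r}")
            self._consumed_on[bid] = on

    def consumed_volume(self) -> float:
        return sum(self._by_id[bid].volume_ml for bid in self._consumed_on)

    def expired_unused_volume(self, asof: date) -> float:
        """Volume that passed expiry without ever being consumed."""
        total = 0.0
        for b in self._bottles:
            if b.expiry_date <= asof and b.bottle_id not in self._consumed_on:
                total += b.volume_ml
        return total

    def leftover_volume(self, asof: date) -> float:
        """Unconsumed, not-yet-expired volume as of a date."""
        total = 0.0
        for b in self._bottles:
            if b.bottle_id not in self._consumed_on and b.expiry_date > asof:
                total += b.volume_ml
        return total


def simulate_arrivals(bottles: list[BottleRecord], horizon_days: int | None = None) -> FreezerTimeline:
    """Build the availability timeline for a set of dated bottles.

    ``horizon_days``, when given, drops bottles arriving after
    ``min(arrival) + horizon_days`` (a finite study window).
    """
    if horizon_days is not None and bottles:
        t0 = min(b.arrival_date for b in bottles)
        cutoff = t0 + timedelta(days=horizon_days)
        bottles = [b for b in bottles if b.arrival_date <= cutoff]
    return FreezerTimeline(bottles)
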