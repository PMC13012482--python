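"""Domain records for the donor-milk pooling pipeline.

The milk bank receives individually expressed frozen donations ("bottles",
roughly 50-250 mL each) and combines them into ~2-litre pools before
pasteurisation.  Concentrations are per 100 mL throughout (crude protein in
g/100 mL, energy in kcal/100 mL), volumes in mL, and dates are day-resolution
:class:`datetime.date` values; those units match how milk banks record and
report composition, and no conversion happens outside the optimiser.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta

from .exceptions import ValidationError

__all__ = ["DonorRecord", "BottleRecord", "PoolRecord", "PoolingConfig"]


@dataclass(frozen=True)
class DonorRecord:
    """One accepted donor and the covariates recorded at first donation.

    ``vegetarian`` is 1 for a vegetarian/vegan diet and 0 for omnivorous;
    ``preterm`` is 1 when the donor delivered before 37 weeks of gestation.
    """

    donor_id: str
    age: float            # years
    bmi: float            # kg/m^2
    vegetarian: int       # {0, 1}
    preterm: int          # {0, 1}
    delivery_date: date

    def __post_init__(self):
        if not self.age > 0:
            raise ValidationError(f"donor {self.donor_id}: age must be > 0, got {self.age}")
        if not self.bmi > 0:
            raise ValidationError(f"donor {self.donor_id}: bmi must be > 0, got {self.bmi}")
        for flag_name in ("vegetarian", "preterm"):
            v = getattr(self, flag_name)
            if v not in (0, 1):
                raise ValidationError(
                    f"donor {self.donor_id}: {flag_name} must be 0 or 1, got {v!r}"
                )


@dataclass(frozen=True)
class BottleRecord:
    """One frozen donation bottle.

    ``crude_protein`` / ``energy`` are optional: they are known only for
    synthetic ground truth or once predicted.  ``expiry_date`` defaults to
    ``arrival_date`` plus the -20 degC storage limit (91 days ~ 3 months).
    """

    bottle_id: str
    donor_id: str
    expression_date: date
    arrival_date: date
    volume_ml: float
    days_postpartum: int | None = None
    crude_protein: float | None = None   # g/100 mL
    energy: float | None = None          # kcal/100 mL
    expiry_date: date | None = None
    storage_limit_days: int = 91

    def __post_init__(self):
        if not self.volume_ml > 0:
            raise ValidationError(
                f"bottle {self.bottle_id}: volume_ml must be > 0, got {self.volume_ml}"
            )
        if self.expiry_date is None:
            object.__setattr__(
                self, "expiry_date", self.arrival_date + timedelta(days=self.storage_limit_days)
            )
        if not (self.expression_date <= self.arrival_date <= self.expiry_date):
            raise ValidationError(
                f"bottle {self.bottle_id}: require expression_date <= arrival_date "
                f"<= expiry_date, got {self.expression_date} / {self.arrival_date} "
                f"/ {self.expiry_date}"
            )
        if self.days_postpartum is not None and self.days_postpartum < 0:
            raise ValidationError(
                f"bottle {self.bottle_id}: days_postpartum must be >= 0, "
                f"got {self.days_postpartum}"
            )
        for name in ("crude_protein", "energy"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(
                    f"bottle {self.bottle_id}: {name} must be > 0 when present, got {v}"
                )

    def with_composition(self, crude_protein: float, energy: float) -> "BottleRecord":
        return dataclasses.replace(self, crude_protein=crude_protein, energy=energy)


@dataclass
class PoolRecord:
    """A realised pool: member bottles, volume-weighted composition, shelf life.

    The shelf life of a pool is set by the member bottle with the shortest
    remaining time before expiration.
    """

    pool_id: str
    bottle_ids: tuple[str, ...]
    donor_ids: frozenset[str]
    total_volume_ml: float
    crude_protein: float | None = None   # volume-weighted, g/100 mL
    energy: float | None = None          # volume-weighted, kcal/100 mL
    shelf_life_date: date | None = None

    @classmethod
    def from_bottles(cls, pool_id: str, bottles: list[BottleRecord]) -> "PoolRecord":
        """Build a pool from bottles with known composition (volume-weighted)."""
        if not bottles:
            raise ValidationError("cannot form a pool from zero bottles")
        vol = sum(b.volume_ml for b in bottles)
        have_comp = all(b.crude_protein is not None and b.energy is not None for b in bottles)
        protein = energy = None
        if have_comp:
            protein = sum(b.volume_ml * b.crude_protein for b in bottles) / vol
            energy = sum(b.volume_ml * b.energy for b in bottles) / vol
        return cls(
            pool_id=pool_id,
            bottle_ids=tuple(b.bottle_id for b in bottles),
            donor_ids=frozenset(b.donor_id for b in bottles),
            total_volume_ml=vol,
            crude_protein=protein,
            energy=energy,
            shelf_life_date=min(b.expiry_date for b in bottles),
        )


@dataclass
class PoolingConfig:
    """All pooling constants in one place.

    Defaults are the operational targets and guideline bounds of the milk
    bank: composition targets 1.0 g crude protein/100 mL and 70 kcal/100 mL,
    pool volume between 2.00 and 2.05 L, three to five distinct donors per
    pool, and a 3-month (91-day) frozen storage limit.  ``priority_weight``
    scales the small expiry-urgency reward in the optimiser objective and
    ``reference_volume_ml`` is the fixed normalisation denominator that keeps
    the deviation objective linear.
    """

    target_protein: float = 1.0       # g/100 mL
    target_energy: float = 70.0       # kcal/100 mL
    vmin_ml: float = 2000.0
    vmax_ml: float = 2050.0
    min_donors: int = 3
    max_donors: int = 5
    n_pools: int = 1
    priority_weight: float = 1e-4
    storage_limit_days: int = 91
    reference_volume_ml: float = 2000.0

    def __post_init__(self):
        if not (0 < self.vmin_ml <= self.vmax_ml):
            raise ValidationError(
                f"require 0 < vmin_ml <= vmax_ml, got {self.vmin_ml} / {self.vmax_ml}"
            )
        if not (1 <= self.min_donors <= self.max_donors):
            raise ValidationError(
                f"require 1 <= min_donors <= max_donors, got "
                f"{self.min_donors} / {self.max_donors}"
            )
        if self.target_protein <= 0 or self.target_energy <= 0:
            raise ValidationError("nutrient targets must be > 0")
        if self.n_pools < 1:
            raise ValidationError(f"n_pools must be >= 1, got {self.n_pools}")
        if self.priority_weight < 0:
            raise ValidationError("priority_weight must be >= 0")
        if self.reference_volume_ml <= 0:
            raise ValidationError("reference_volume_ml must be > 0")

    def replace(self, **kwargs) -> "PoolingConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def targets(self) -> dict[str, float]:
        return {"protein": self.target_protein, "energy": self.target_energy}
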