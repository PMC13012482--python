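"""CSV input/output for donor cohorts, pools, and pooling configuration.

File schemas (all plain CSV, ISO-8601 dates):

``donors.csv``
    donor_id, age_y, bmi, vegetarian, preterm, delivery_date

``bottles.csv``
    bottle_id, donor_id, expression_date, arrival_date, volume_ml,
    crude_protein_g_100ml (optional), energy_kcal_100ml (optional)

``pools.csv`` (assignment report output)
    pool_id, bottle_ids (semicolon-joined), n_donors, volume_ml,
    protein_g_100ml, energy_kcal_100ml, dev_protein, dev_energy,
    shelf_life_date — plus one trailing summary row.

Config files are flat ``key = value`` text; unspecified keys take the
:class:`~milkpool.records.PoolingConfig` defaults.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .exceptions import ReferentialError, SchemaError, ValidationError
from .records import BottleRecord, DonorRecord, PoolingConfig

if TYPE_CHECKING:  # pragma: no cover
    from .optimise import PoolAssignment

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_assignment_report",
    "read_assignment_report",
    "load_config",
]

DONOR_COLUMNS = ["donor_id", "age_y", "bmi", "vegetarian", "preterm", "delivery_date"]
BOTTLE_COLUMNS = ["bottle_id", "donor_id", "expression_date", "arrival_date", "volume_ml"]
_OPTIONAL_BOTTLE_COLUMNS = ["crude_protein_g_100ml", "energy_kcal_100ml"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_date(value, context: str) -> date:
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"{context}: bad ISO date {value!r}") from exc


def read_cohort(
    donors_path, bottles_path, storage_limit_days: int = 91
) -> tuple[list[DonorRecord], list[BottleRecord]]:
    """Read a donor cohort from ``donors.csv`` + ``bottles.csv``.

    Every bottle's donor must exist in the donors file; ``days_postpartum``
    is computed from expression and delivery dates when not supplied.
    Bottles are returned sorted by arrival date (the order the freezer
    receives them).
    """
    donors_df = pd.read_csv(donors_path, dtype={"donor_id": str})
    bottles_df = pd.read_csv(bottles_path, dtype={"bottle_id": str, "donor_id": str})
    _require_columns(donors_df, DONOR_COLUMNS, donors_path)
    _require_columns(bottles_df, BOTTLE_COLUMNS, bottles_path)

    donors = [
        DonorRecord(
            donor_id=row.donor_id,
            age=float(row.age_y),
            bmi=float(row.bmi),
            vegetarian=int(row.vegetarian),
            preterm=int(row.preterm),
            delivery_date=_parse_date(row.delivery_date, f"donor {row.donor_id}"),
        )
        for row in donors_df.itertuples(index=False)
    ]
    by_id = {d.donor_id: d for d in donors}

    bottles: list[BottleRecord] = []
    for row in bottles_df.itertuples(index=False):
        donor = by_id.get(row.donor_id)
        if donor is None:
            raise ReferentialError(
                f"bottle {row.bottle_id}: unknown donor_id {row.donor_id!r}"
            )
        expression = _parse_date(row.expression_date, f"bottle {row.bottle_id}")
        arrival = _parse_date(row.arrival_date, f"bottle {row.bottle_id}")
        kwargs = {}
        for col, attr in zip(_OPTIONAL_BOTTLE_COLUMNS, ("crude_protein", "energy")):
            if col in bottles_df.columns:
                v = getattr(row, col)
                if pd.notna(v):
                    kwargs[attr] = float(v)
        bottles.append(
            BottleRecord(
                bottle_id=row.bottle_id,
                donor_id=row.donor_id,
                expression_date=expression,
                arrival_date=arrival,
                volume_ml=float(row.volume_ml),
                days_postpartum=(expression - donor.delivery_date).days,
                storage_limit_days=storage_limit_days,
                **kwargs,
            )
        )
    bottles.sort(key=lambda b: (b.arrival_date, b.bottle_id))
    return donors, bottles


def write_cohort(donors: list[DonorRecord], bottles: list[BottleRecord],
                 donors_path, bottles_path) -> None:
    """Write a cohort back to the documented CSV schemas (lossless round-trip)."""
    pd.DataFrame(
        {
            "donor_id": [d.donor_id for d in donors],
            "age_y": [round(d.age, 6) for d in donors],
            "bmi": [round(d.bmi, 6) for d in donors],
            "vegetarian": [d.vegetarian for d in donors],
            "preterm": [d.preterm for d in donors],
            "delivery_date": [d.delivery_date.isoformat() for d in donors],
        }
    ).to_csv(donors_path, index=False)
    pd.DataFrame(
        {
            "bottle_id": [b.bottle_id for b in bottles],
            "donor_id": [b.donor_id for b in bottles],
            "expression_date": [b.expression_date.isoformat() for b in bottles],
            "arrival_date": [b.arrival_date.isoformat() for b in bottles],
            "volume_ml": [round(b.volume_ml, 6) for b in bottles],
            "crude_protein_g_100ml": [
                None if b.crude_protein is None else round(b.crude_protein, 6)
                for b in bottles
            ],
            "energy_kcal_100ml": [
                None if b.energy is None else round(b.energy, 6) for b in bottles
            ],
        }
    ).to_csv(bottles_path, index=False)


def write_assignment_report(assignment: "PoolAssignment", path) -> None:
    """Write an evaluated assignment as ``pools.csv`` plus a summary row.

    The summary row (pool_id ``"TOTAL"``) carries the pooled volume, the
    total donor count, volume-weighted mean composition and the summed
    deviations; numeric fields round-trip to 6 decimals.
    """
    rows = []
    for pool in assignment.pools:
        rows.append(
            {
                "pool_id": pool.pool_id,
                "bottle_ids": ";".join(pool.bottle_ids),
                "n_donors": len(pool.donor_ids),
                "volume_ml": round(pool.total_volume_ml, 6),
                "protein_g_100ml": round(pool.crude_protein, 6),
                "energy_kcal_100ml": round(pool.energy, 6),
                "dev_protein": round(assignment.dev_protein[pool.pool_id], 6),
                "dev_energy": round(assignment.dev_energy[pool.pool_id], 6),
                "shelf_life_date": pool.shelf_life_date.isoformat(),
            }
        )
    total_volume = sum(p.total_volume_ml for p in assignment.pools)
    if total_volume > 0:
        mean_protein = sum(p.crude_protein * p.total_volume_ml for p in assignment.pools) / total_volume
        mean_energy = sum(p.energy * p.total_volume_ml for p in assignment.pools) / total_volume
        shelf = min(p.shelf_life_date for p in assignment.pools).isoformat()
    else:
        mean_protein = mean_energy = 0.0
        shelf = ""
    rows.append(
        {
            "pool_id": "TOTAL",
            "bottle_ids": "",
            "n_donors": len({d for p in assignment.pools for d in p.donor_ids}),
            "volume_ml": round(total_volume, 6),
            "protein_g_100ml": round(mean_protein, 6),
            "energy_kcal_100ml": round(mean_energy, 6),
            "dev_protein": round(sum(assignment.dev_protein.values()), 6),
            "dev_energy": round(sum(assignment.dev_energy.values()), 6),
            "shelf_life_date": shelf,
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignment_report(path) -> pd.DataFrame:
    """Read ``pools.csv`` back; the TOTAL summary row is kept as the last row."""
    if not Path(path).exists():
        raise SchemaError(f"assignment report not found: {path}")
    return pd.read_csv(path, dtype={"pool_id": str}, keep_default_na=False)


_CONFIG_FIELD_TYPES = {
    "target_protein": float,
    "target_energy": float,
    "vmin_ml": float,
    "vmax_ml": float,
    "min_donors": int,
    "max_donors": int,
    "n_pools": int,
    "priority_weight": float,
    "storage_limit_days": int,
    "reference_volume_ml": float,
}


def load_config(path, **overrides) -> PoolingConfig:
    """Load a :class:`PoolingConfig` from a flat ``key = value`` text file.

    Blank lines and ``#`` comments are ignored; ``key: value`` is also
    accepted.  Keys not present in the file keep their defaults; keyword
    ``overrides`` win over file values.  Invariants are enforced by the
    config's own validation.
    """
    values: dict = {}
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise SchemaError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key = key.strip()
        if key not in _CONFIG_FIELD_TYPES:
            raise SchemaError(f"{path}:{lineno}: unknown config key {key!r}")
        try:
            values[key] = _CONFIG_FIELD_TYPES[key](value.strip())
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: bad value for {key}: {value!r}") from exc
    values.update(overrides)
    return PoolingConfig(**values)
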