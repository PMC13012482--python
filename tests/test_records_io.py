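"""Domain record invariants and CSV round-trips."""

from datetime import date

import pandas as pd
import pytest

from milkpool import (
    BottleRecord,
    DonorRecord,
    PoolingConfig,
    PoolRecord,
    load_config,
    read_cohort,
    write_assignment_report,
    write_cohort,
)
from milkpool.cohort_io import read_assignment_report
from milkpool.exceptions import ReferentialError, SchemaError, ValidationError
from milkpool.optimise import evaluate_assignment


def _donor(donor_id="D1", **kw):
    defaults = dict(age=30.0, bmi=24.0, vegetarian=0, preterm=0,
                    delivery_date=date(2023, 1, 1))
    defaults.update(kw)
    return DonorRecord(donor_id=donor_id, **defaults)


def _bottle(bottle_id="B1", donor_id="D1", **kw):
    defaults = dict(expression_date=date(2023, 2, 1), arrival_date=date(2023, 2, 5),
                    volume_ml=200.0, days_postpartum=31)
    defaults.update(kw)
    return BottleRecord(bottle_id=bottle_id, donor_id=donor_id, **defaults)


class TestRecordInvariants:
    @pytest.mark.parametrize(
        "kw",
        [dict(age=-1.0), dict(bmi=0.0), dict(vegetarian=2), dict(preterm=-1)],
    )
    def test_bad_donor_rejected(self, kw):
        with pytest.raises(ValidationError):
            _donor(**kw)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(volume_ml=0.0),
            dict(expression_date=date(2023, 3, 1)),  # after arrival
            dict(days_postpartum=-3),
            dict(crude_protein=-0.5),
            dict(energy=0.0),
        ],
    )
    def test_bad_bottle_rejected(self, kw):
        with pytest.raises(ValidationError):
            _bottle(**kw)

    def test_expiry_defaults_to_storage_limit(self):
        b = _bottle()
        assert (b.expiry_date - b.arrival_date).days == 91

    def test_pool_aggregates_members(self):
        bottles = [
            _bottle("B1", "D1", crude_protein=0.8, energy=65.0, volume_ml=1000.0),
            _bottle("B2", "D2", crude_protein=1.2, energy=75.0, volume_ml=1000.0,
                    arrival_date=date(2023, 2, 9)),
        ]
        pool = PoolRecord.from_bottles("P1", bottles)
        assert pool.total_volume_ml == pytest.approx(2000.0)
        assert pool.donor_ids == {"D1", "D2"}
        # volume-weighted mean of a 50/50 mix
        assert pool.crude_protein == pytest.approx(1.0)
        assert pool.energy == pytest.approx(70.0)
        assert pool.shelf_life_date == min(b.expiry_date for b in bottles)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(vmin_ml=2100.0, vmax_ml=2050.0),
            dict(min_donors=6, max_donors=5),
            dict(target_protein=0.0),
            dict(n_pools=0),
        ],
    )
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValidationError):
            PoolingConfig(**kw)


class TestCohortIO:
    def _write_fixture(self, tmp_path, bottle_rows=None):
        donors = pd.DataFrame(
            {
                "donor_id": ["D1", "D2"],
                "age_y": [30.0, 35.5],
                "bmi": [22.0, 27.3],
                "vegetarian": [0, 1],
                "preterm": [1, 0],
                "delivery_date": ["2023-01-01", "2023-01-10"],
            }
        )
        if bottle_rows is None:
            bottle_rows = [
                ("B1", "D1", "2023-02-01", "2023-02-05", 200.0),
                ("B2", "D2", "2023-02-02", "2023-02-03", 150.0),
                ("B3", "D1", "2023-02-03", "2023-02-08", 250.0),
            ]
        bottles = pd.DataFrame(
            bottle_rows,
            columns=["bottle_id", "donor_id", "expression_date", "arrival_date", "volume_ml"],
        )
        dp, bp = tmp_path / "donors.csv", tmp_path / "bottles.csv"
        donors.to_csv(dp, index=False)
        bottles.to_csv(bp, index=False)
        return dp, bp

    def test_round_trip(self, tmp_path):
        dp, bp = self._write_fixture(tmp_path)
        donors, bottles = read_cohort(dp, bp)
        assert len(donors) == 2 and len(bottles) == 3
        # sorted by arrival date and days postpartum computed
        assert [b.bottle_id for b in bottles] == ["B2", "B1", "B3"]
        assert bottles[1].days_postpartum == 31
        # write back and re-read: identical numerics
        write_cohort(donors, bottles, tmp_path / "d2.csv", tmp_path / "b2.csv")
        donors2, bottles2 = read_cohort(tmp_path / "d2.csv", tmp_path / "b2.csv")
        assert donors == donors2
        assert [b.volume_ml for b in bottles] == [b.volume_ml for b in bottles2]

    def test_unknown_donor_is_referential_error(self, tmp_path):
        dp, bp = self._write_fixture(
            tmp_path, [("B1", "D99", "2023-02-01", "2023-02-05", 200.0)]
        )
        with pytest.raises(ReferentialError, match="D99"):
            read_cohort(dp, bp)

    def test_expression_after_arrival_rejected(self, tmp_path):
        dp, bp = self._write_fixture(
            tmp_path, [("B1", "D1", "2023-02-10", "2023-02-05", 200.0)]
        )
        with pytest.raises(ValidationError):
            read_cohort(dp, bp)

    def test_missing_column_named(self, tmp_path):
        dp, bp = self._write_fixture(tmp_path)
        df = pd.read_csv(bp).drop(columns=["volume_ml"])
        df.to_csv(bp, index=False)
        with pytest.raises(SchemaError, match="volume_ml"):
            read_cohort(dp, bp)


class TestAssignmentReport:
    def _assignment(self):
        members = {
            "P000": [
                _bottle("B1", "D1", crude_protein=1.02, energy=68.0, volume_ml=1000.0),
                _bottle("B2", "D2", crude_protein=0.95, energy=72.0, volume_ml=1010.0),
            ],
            "P001": [
                _bottle("B3", "D3", crude_protein=1.1, energy=70.0, volume_ml=2040.0),
            ],
        }
        return evaluate_assignment(members, None, PoolingConfig(min_donors=1))

    def test_report_has_pool_rows_plus_summary(self, tmp_path):
        path = tmp_path / "pools.csv"
        write_assignment_report(self._assignment(), path)
        df = read_assignment_report(path)
        assert len(df) == 3
        assert df.iloc[-1]["pool_id"] == "TOTAL"

    def test_numeric_round_trip_to_6_decimals(self, tmp_path):
        assignment = self._assignment()
        path = tmp_path / "pools.csv"
        write_assignment_report(assignment, path)
        df = read_assignment_report(path).set_index("pool_id")
        for pool in assignment.pools:
            row = df.loc[pool.pool_id]
            assert float(row.volume_ml) == pytest.approx(pool.total_volume_ml, abs=1e-6)
            assert float(row.protein_g_100ml) == pytest.approx(pool.crude_protein, abs=1e-6)
            assert float(row.dev_protein) == pytest.approx(
                assignment.dev_protein[pool.pool_id], abs=1e-6
            )

    def test_empty_assignment_writes_summary_only(self, tmp_path):
        empty = evaluate_assignment({}, None, PoolingConfig())
        path = tmp_path / "pools.csv"
        write_assignment_report(empty, path)
        df = read_assignment_report(path)
        assert len(df) == 1 and df.iloc[0]["pool_id"] == "TOTAL"


class TestConfigFile:
    def test_empty_config_gives_bank_defaults(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("# all defaults\n")
        cfg = load_config(p)
        assert cfg.target_protein == 1.0
        assert cfg.target_energy == 70.0
        assert (cfg.vmin_ml, cfg.vmax_ml) == (2000.0, 2050.0)
        assert (cfg.min_donors, cfg.max_donors) == (3, 5)
        assert cfg.storage_limit_days == 91

    def test_partial_override(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("n_pools = 10\n")
        cfg = load_config(p)
        assert cfg.n_pools == 10
        assert cfg.target_protein == 1.0

    def test_inconsistent_bounds_rejected(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("min_donors = 6\nmax_donors = 5\n")
        with pytest.raises(ValidationError):
            load_config(p)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("frobnicate = 3\n")
        with pytest.raises(SchemaError, match="frobnicate"):
            load_config(p)
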