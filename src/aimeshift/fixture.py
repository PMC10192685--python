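"""Packaged published-results fixture and its summary-count verification.

The package ships the 25-chemical screen summary (expected classification,
concordance flag, hit-calls, efficacy and BMD per metabolism mode) as a
CSV fixture. Recomputing the screen-level tallies from its columns checks
the counting logic against the published summary statistics without any
raw well data.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .errors import FixtureError
from .shift import ExpectedClass, ShiftRecord, SummaryCounts, score_concordance

_EXPECTED_ROWS = 25
_NUMERIC_COLS = ("hitc_met_neg", "hitc_met_pos", "max_med_met_neg", "max_med_met_pos")


def parse_bmd(value: str) -> tuple[float, bool]:
    """Parse a BMD cell -> (value, censored).

    "NA" -> (NaN, False); ">200"-style bounds -> (bound, True), meaning no
    benchmark crossing within the tested range.
    """
    s = str(value).strip()
    if s.upper() == "NA":
        return math.nan, False
    if s.startswith(">"):
        return float(s[1:]), True
    return float(s), False


def load_printed_results() -> pd.DataFrame:
    """Load and validate the packaged 25-row screen-summary fixture."""
    with resources.files("aimeshift.data").joinpath("printed_results.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return validate_fixture(df)


def validate_fixture(df: pd.DataFrame) -> pd.DataFrame:
    """Integrity checks: row count, enums, flags, sentinel parsing."""
    if len(df) != _EXPECTED_ROWS:
        raise FixtureError(f"fixture has {len(df)} rows, expected {_EXPECTED_ROWS}")
    valid_classes = {e.value for e in ExpectedClass}
    bad = set(df["classification"]) - valid_classes
    if bad:
        raise FixtureError(f"unknown classification values {bad}")
    if not set(df["concordance"]) <= {"0", "1"}:
        raise FixtureError("concordance flags must be 0/1")
    for col in _NUMERIC_COLS:
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise FixtureError(f"non-numeric value in {col}: {exc}") from exc
    for col in ("bmd_met_neg", "bmd_met_pos"):
        df[[col, col + "_censored"]] = pd.DataFrame(
            [parse_bmd(v) for v in df[col]], index=df.index
        )
    df["concordance"] = df["concordance"].astype(int)
    return df


def fixture_shift_records(
    fixture: pd.DataFrame, threshold: float = 0.9
) -> list[ShiftRecord]:
    """Reconstruct per-chemical shift records from the fixture columns.

    The fixture reports no AUCs; the ΔAUC direction of each
    biotransformation-classified chemical is implied by its class and
    printed concordance flag (a concordant Bioactivated row shifted
    positive, a non-concordant one negative, and vice versa). Agonist-class
    rows keep the printed flag with an undetermined direction.
    """
    records: list[ShiftRecord] = []
    for t in fixture.itertuples(index=False):
        cls = ExpectedClass(t.classification)
        conc_flag = bool(t.concordance)
        if cls is ExpectedClass.BIOACTIVATED:
            direction = "activated" if conc_flag else "inactivated"
        elif cls is ExpectedClass.BIOINACTIVATED:
            direction = "inactivated" if conc_flag else "activated"
        else:
            direction = "no_change"
        delta = {"activated": 1.0, "inactivated": -1.0, "no_change": 0.0}[direction]
        hn, hp = float(t.hitc_met_neg), float(t.hitc_met_pos)
        records.append(
            ShiftRecord(
                chemical_id=str(t.chemical),
                auc_neg=0.0,
                auc_pos=delta,
                delta_auc=delta,
                direction=direction,
                hitc_neg=hn,
                hitc_pos=hp,
                active_any=(hn >= threshold) or (hp >= threshold),
                active_both=(hn >= threshold) and (hp >= threshold),
                expected_class=cls,
                concordant=conc_flag,
            )
        )
    return records


def verify_fixture_counts(
    fixture: pd.DataFrame | None = None, threshold: float = 0.9
) -> SummaryCounts:
    """Recompute all screen-level summary counts from the fixture columns."""
    if fixture is None:
        fixture = load_printed_results()
    records = fixture_shift_records(fixture, threshold)
    counts = score_concordance(records)
    return counts
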