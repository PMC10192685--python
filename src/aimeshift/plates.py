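"""Plate/well data model, CSV well-table IO, layout and dosing arithmetic.

A 384-well plate is 16 rows × 24 columns, 1-based (row 1 = A). The assay
runs both metabolism modes on one plate: metabolism-negative microspheres
occupy rows 2–8 and metabolism-positive microspheres rows 9–15; rows 1 and
16 hold no-microsphere baseline wells. Three columns are reserved for
plate controls, leaving 21 test columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LayoutError, PlateConfigError, PlateParseError


class Mode(str, Enum):
    """Metabolism mode of a well."""

    NO_MET = "NoMet"      # no microspheres (baseline rows)
    MET_NEG = "MetNeg"    # water-alginate microspheres: no metabolism
    MET_POS = "MetPos"    # S9-alginate microspheres: hepatic metabolism

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Solvent-control name used for baseline wells.
DMSO = "DMSO"

#: Printed 1X test-concentration series (µM), lowest to highest.
PRINTED_1X_LEVELS_UM: tuple[float, ...] = (
    0.00249, 0.1605, 1.245, 4.98, 14.95, 33.6, 67.0, 119.5, 199.0,
)

#: Effective acoustic-dispense volume (nL) per level that reproduces the
#: printed series from a 100 mM stock with DMSO backfill to 400 nL into
#: 100 µL medium and 1:1 transfer to cells.
DEFAULT_DISPENSE_NL: tuple[float, ...] = (
    0.005, 0.3223, 2.5, 10.0, 30.0, 67.5, 135.0, 240.0, 400.0,
)


@dataclass(frozen=True)
class WellRecord:
    """One well: identity, dose, metabolism mode, raw signal, quality flag."""

    plate_id: str
    row: int
    col: int
    chemical_id: str
    conc: float          # µM; 0 for solvent control
    mode: Mode
    raw_lum: float       # relative light units, >= 0
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.row <= 16):
            raise PlateConfigError(f"row {self.row} outside 1..16")
        if not (1 <= self.col <= 24):
            raise PlateConfigError(f"col {self.col} outside 1..24")
        if self.conc < 0:
            raise PlateConfigError(f"negative concentration {self.conc}")
        if self.raw_lum < 0:
            raise PlateConfigError(f"negative raw signal {self.raw_lum}")


@dataclass(frozen=True)
class PlateLayout:
    """Plate geometry: mode bands per row range, control and test columns.

    ``mode_bands`` maps inclusive row ranges to modes. ``control_wells``
    maps a control name to its (row, col) positions. ``test_columns`` are
    the columns available to test chemicals (21 by default; columns 1–3
    are reserved for controls, a configurable choice — the assay design
    fixes only their number).
    """

    mode_bands: Mapping[tuple[int, int], Mode] = field(
        default_factory=lambda: {(2, 8): Mode.MET_NEG, (9, 15): Mode.MET_POS}
    )
    control_wells: Mapping[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    test_columns: tuple[int, ...] = tuple(range(4, 25))
    baseline_rows: tuple[int, ...] = (1, 16)   # no-microsphere DMSO rows

    def __post_init__(self) -> None:
        control_positions = {p for pos in self.control_wells.values() for p in pos}
        seen: set[tuple[int, int]] = set()
        for p in (p for pos in self.control_wells.values() for p in pos):
            if p in seen:
                raise PlateConfigError(f"control position {p} assigned twice")
            seen.add(p)
        for col in self.test_columns:
            if not (1 <= col <= 24):
                raise PlateConfigError(f"test column {col} outside 1..24")
        for (lo, hi) in self.mode_bands:
            if lo > hi:
                raise PlateConfigError(f"empty mode band {(lo, hi)}")
        # test wells (band rows x test columns) must not collide with controls
        for (lo, hi) in self.mode_bands:
            for row in range(lo, hi + 1):
                for col in self.test_columns:
                    if (row, col) in control_positions:
                        raise PlateConfigError(
                            f"control well {(row, col)} inside a test column"
                        )

    def band_mode(self, row: int) -> Mode | None:
        for (lo, hi), mode in self.mode_bands.items():
            if lo <= row <= hi:
                return mode
        if row in self.baseline_rows:
            return Mode.NO_MET
        return None

    def control_name_at(self, row: int, col: int) -> str | None:
        for name, positions in self.control_wells.items():
            if (row, col) in positions:
                return name
        return None


def default_layout() -> PlateLayout:
    """Standard layout: DMSO in column 1, the ER-agonist reference
    (17β-estradiol) in column 2, the bioinactivation (ethylparaben) and
    bioactivation (trans-Stilbene) metabolism controls interleaved in
    column 3, and DMSO baseline in rows 1 and 16 across all columns."""
    band_rows = list(range(2, 16))
    dmso = tuple((r, 1) for r in band_rows)
    dmso += tuple((r, c) for r in (1, 16) for c in range(1, 25))
    e2 = tuple((r, 2) for r in band_rows)
    ep = tuple((r, 3) for r in band_rows if r % 2 == 0)
    ts = tuple((r, 3) for r in band_rows if r % 2 == 1)
    return PlateLayout(
        control_wells={
            DMSO: dmso,
            "17beta-estradiol": e2,
            "ethylparaben": ep,
            "trans-stilbene": ts,
        }
    )


@dataclass(frozen=True)
class DoseSeries:
    """The acoustic-dispense dosing design producing the 1X test series.

    A 100 mM DMSO stock is dispensed at per-level volumes, backfilled with
    DMSO to 400 nL, into 100 µL of cofactor-supplemented medium (2X
    concentrations); metabolism proceeds at 2X and the conditioned medium
    is added 1:1 to cells, halving every level to its final 1X value.
    """

    stock_mM: float = 100.0
    dispense_nL: tuple[float, ...] = DEFAULT_DISPENSE_NL
    medium_uL: float = 100.0
    backfill_to_nL: float = 400.0
    transfer_dilution: float = 2.0
    sig_figs: int = 3

    def __post_init__(self) -> None:
        levels = self.levels_1x_uM()
        if len(levels) != 9:
            raise PlateConfigError(f"dose series has {len(levels)} levels, expected 9")
        if not all(a < b for a, b in zip(levels, levels[1:])):
            raise PlateConfigError("dose levels must be strictly increasing")

    def levels_1x_uM(self) -> tuple[float, ...]:
        return tuple(
            final_concentration_series(
                self.stock_mM,
                self.dispense_nL,
                self.medium_uL,
                backfill_to_nL=self.backfill_to_nL,
                dilution_factor=self.transfer_dilution,
                sig_figs=self.sig_figs,
            )
        )


def _round_sig(x: float, sig: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def final_concentration_series(
    stock_mM: float,
    dispense_nL: float | Sequence[float],
    medium_uL: float,
    backfill_to_nL: float | None = None,
    dilution_factor: float = 1.0,
    sig_figs: int = 3,
) -> list[float]:
    """Final test concentrations (µM) from acoustic-dispense volumes.

    Each level is (dispensed stock moles) / (medium volume + dispensed
    volume), divided by ``dilution_factor`` (1:1 transfer to cells = 2),
    rounded to ``sig_figs`` significant figures. When ``backfill_to_nL``
    is given, every well is backfilled with solvent to that total dispense
    volume, so the diluting volume is medium + backfill regardless of the
    chemical's own volume (the backfill is inert: it changes the DMSO
    fraction, not the chemical's molarity).
    """
    if stock_mM <= 0 or medium_uL <= 0 or dilution_factor <= 0:
        raise PlateConfigError("stock, medium volume and dilution factor must be > 0")
    volumes = [dispense_nL] if np.isscalar(dispense_nL) else list(dispense_nL)
    out = []
    for d in volumes:
        d = float(d)
        if d <= 0:
            raise PlateConfigError(f"nonpositive dispense volume {d} nL")
        total_nL = d if backfill_to_nL is None else float(backfill_to_nL)
        if total_nL < d:
            raise PlateConfigError("backfill target smaller than dispensed volume")
        moles = stock_mM * 1e-3 * d * 1e-9            # mol
        vol_L = medium_uL * 1e-6 + total_nL * 1e-9    # L
        conc_uM = moles / vol_L * 1e6 / dilution_factor
        out.append(_round_sig(conc_uM, sig_figs))
    return out


def assign_mode(record: WellRecord, layout: PlateLayout) -> WellRecord:
    """Set a well's metabolism mode from its row band.

    Control wells keep the mode of the band they sit in (baseline rows map
    to ``NoMet``). A row outside every band that is not a control position
    raises :class:`LayoutError`.
    """
    mode = layout.band_mode(record.row)
    if mode is None:
        if layout.control_name_at(record.row, record.col) is None:
            raise LayoutError(
                f"well ({record.row}, {record.col}) on plate {record.plate_id} "
                "is outside all mode bands and is not a control position"
            )
        mode = Mode.NO_MET
    return replace(record, mode=mode)


# ---------------------------------------------------------------------------
# CSV well-table IO

#: Canonical column names; a dialect maps these to the file's own headers.
CANONICAL_COLUMNS = (
    "plate_id", "row", "col", "chemical_id", "conc", "mode", "raw_lum", "quality_ok",
)

_TRUTHY = {"true", "1", "yes", "ok", "t", "y"}
_FALSY = {"false", "0", "no", "fail", "f", "n"}


def _parse_bool(val: object) -> bool:
    if isinstance(val, (bool, np.bool_)):
        return bool(val)
    s = str(val).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"unrecognized boolean {val!r}")


def read_plate_table(
    path, dialect: Mapping[str, str] | None = None
) -> list[WellRecord]:
    """Read a well-level CSV table into :class:`WellRecord` objects.

    ``dialect`` maps canonical column names to the file's header names
    (defaults to the canonical names themselves). Malformed cells are
    reported with their 1-based data row numbers.
    """
    dialect = dict(dialect or {})
    colmap = {c: dialect.get(c, c) for c in CANONICAL_COLUMNS}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise PlateConfigError(f"{path}: missing required columns {missing}")

    records: list[WellRecord] = []
    problems: list[str] = []
    for i in range(len(df)):
        raw = {c: df.iloc[i][v] for c, v in colmap.items()}
        try:
            records.append(
                WellRecord(
                    plate_id=str(raw["plate_id"]),
                    row=int(raw["row"]),
                    col=int(raw["col"]),
                    chemical_id=str(raw["chemical_id"]),
                    conc=float(raw["conc"]),
                    mode=Mode(raw["mode"]),
                    raw_lum=float(raw["raw_lum"]),
                    quality_ok=_parse_bool(raw["quality_ok"]),
                )
            )
        except (ValueError, KeyError, PlateConfigError) as exc:
            problems.append(f"row {i + 1}: {exc}")
    if problems:
        raise PlateParseError(
            f"{path}: {len(problems)} malformed row(s): " + "; ".join(problems[:10])
        )
    return records


def wells_to_frame(records: Iterable[WellRecord]) -> pd.DataFrame:
    """Tabular view of well records (one row per well)."""
    records = list(records)
    return pd.DataFrame(
        {
            "plate_id": [r.plate_id for r in records],
            "row": [r.row for r in records],
            "col": [r.col for r in records],
            "chemical_id": [r.chemical_id for r in records],
            "conc": [r.conc for r in records],
            "mode": [r.mode.value for r in records],
            "raw_lum": [r.raw_lum for r in records],
            "quality_ok": [r.quality_ok for r in records],
        }
    )


def frame_to_wells(df: pd.DataFrame) -> list[WellRecord]:
    return [
        WellRecord(
            plate_id=str(t.plate_id),
            row=int(t.row),
            col=int(t.col),
            chemical_id=str(t.chemical_id),
            conc=float(t.conc),
            mode=Mode(t.mode),
            raw_lum=float(t.raw_lum),
            quality_ok=bool(t.quality_ok),
        )
        for t in df.itertuples(index=False)
    ]


def write_plate_table(records: Iterable[WellRecord] | pd.DataFrame, path) -> None:
    """Write well records as a canonical-dialect CSV (UTF-8, header row)."""
    df = records if isinstance(records, pd.DataFrame) else wells_to_frame(list(records))
    df.to_csv(path, index=False)
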