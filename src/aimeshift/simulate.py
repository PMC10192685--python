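"""Synthetic 384-well ERTA plate generator with ground truth.

Emulates the screen's structure: each plate carries both metabolism modes
(Met Neg rows 2–8, Met Pos rows 9–15), the 9-level 1X dose series, DMSO
solvent baseline, an ER-agonist reference partially inactivated by
metabolism, a bioinactivated control and a bioactivated control; each
chemical is a single technical replicate per plate and the experiment has
4 replicate plates by default.

Signal model: ``raw = bval · plate_scale · (1 + true_resp) · e^ε`` with
ε ~ Normal(0, σ) — multiplicative lognormal well noise, the dominant
error mode of luminescence readouts — floored at zero. Sparse dispense
failures flag wells low-quality at a configurable rate. One random stream
is derived per plate from (seed, plate index) so individual plates are
independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import PlateConfigError
from .models import eval_model
from .plates import (
    DMSO,
    DoseSeries,
    Mode,
    PlateLayout,
    default_layout,
)
from .shift import ExpectedClass


@dataclass(frozen=True)
class ChemicalTruth:
    """Generating curve for one chemical plus its metabolism effect.

    The Met Neg response is the named model; Met Pos multiplies the
    amplitude (``tp``/``a``) by ``tp_multiplier`` and shifts log10 potency
    by ``ga_log10_shift``. ``expected_class`` must agree with the effect
    direction when directional.
    """

    model: str
    params: dict[str, float]
    tp_multiplier: float = 1.0
    ga_log10_shift: float = 0.0
    expected_class: ExpectedClass | None = None

    def __post_init__(self) -> None:
        if self.tp_multiplier <= 0:
            raise PlateConfigError("tp_multiplier must be > 0")
        if self.expected_class is ExpectedClass.BIOACTIVATED and self.tp_multiplier <= 1:
            raise PlateConfigError("Bioactivated truth needs multiplier > 1")
        if self.expected_class is ExpectedClass.BIOINACTIVATED and self.tp_multiplier >= 1:
            raise PlateConfigError("Bioinactivated truth needs multiplier < 1")

    def true_resp(self, conc: np.ndarray, mode: Mode) -> np.ndarray:
        params = dict(self.params)
        if mode is Mode.MET_POS:
            for amp in ("tp", "a"):
                if amp in params:
                    params[amp] *= self.tp_multiplier
            for pot in ("ga", "b"):
                if pot in params:
                    params[pot] *= 10.0 ** self.ga_log10_shift
        return eval_model(self.model, params, np.asarray(conc, float))


#: Control true responses (zero-centered fold-change at the plated dose) and
#: metabolism multipliers matching the reference chemicals' qualitative
#: behaviour: the agonist and the bioinactivated control lose ~78–79% of
#: their activity with metabolism, the bioactivated control gains ~136%.
DEFAULT_CONTROL_TRUTH: Mapping[str, tuple[float, float]] = {
    "17beta-estradiol": (5.0, 0.220),
    "ethylparaben": (2.0, 0.208),
    "trans-stilbene": (1.0, 2.361),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Full ground truth for one synthetic experiment."""

    chemicals: dict[str, ChemicalTruth]
    noise_sd: float = 0.1           # lognormal sigma of well noise
    bval: float = 10000.0           # nominal baseline, relative light units
    plate_scale_range: tuple[float, float] = (0.8, 1.25)
    dropout_rate: float = 0.01      # sparse dispense-failure probability
    control_truth: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_TRUTH))
    control_conc_uM: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 0.2:
            raise PlateConfigError("dropout_rate outside [0, 0.2]")
        if self.noise_sd < 0:
            raise PlateConfigError("noise_sd must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["chemicals"] = {
            k: {**asdict(v), "expected_class":
                v.expected_class.value if v.expected_class else None}
            for k, v in self.chemicals.items()
        }
        return json.dumps(d, indent=2, default=str)


def default_truth(n_chemicals: int = 6, seed: int = 0,
                  noise_sd: float = 0.1) -> SyntheticTruth:
    """A mixed panel of hill-curve chemicals with bidirectional effects."""
    rng = np.random.default_rng(seed)
    chems: dict[str, ChemicalTruth] = {}
    for i in range(n_chemicals):
        mult = float(rng.choice([0.25, 0.5, 1.0, 2.0, 4.0]))
        if mult > 1:
            cls = ExpectedClass.BIOACTIVATED
        elif mult < 1:
            cls = ExpectedClass.BIOINACTIVATED
        else:
            cls = ExpectedClass.AGONIST
        chems[f"chem{i:02d}"] = ChemicalTruth(
            model="hill",
            params={"tp": float(rng.uniform(1.0, 3.0)),
                    "ga": float(10.0 ** rng.uniform(0.0, 1.5)),
                    "p": float(rng.uniform(1.0, 2.0))},
            tp_multiplier=mult,
            expected_class=cls,
        )
    return SyntheticTruth(chemicals=chems, noise_sd=noise_sd, seed=seed)


def _chemical_slots(layout: PlateLayout, dose_levels: int, n_chemicals: int):
    """Assign each chemical a (band-row-offset, column-block) slot.

    A chemical's 9-level series runs along one band row across a block of
    test columns; the same slot is used in both mode bands so each plate
    carries the chemical in Met Neg and Met Pos.
    """
    bands = sorted(layout.mode_bands.items())
    n_rows = min(hi - lo + 1 for (lo, hi), _ in bands)
    blocks = [
        layout.test_columns[i: i + dose_levels]
        for i in range(0, len(layout.test_columns) - dose_levels + 1, dose_levels)
    ]
    capacity = n_rows * len(blocks)
    if n_chemicals > capacity:
        raise PlateConfigError(
            f"{n_chemicals} chemicals exceed plate capacity {capacity}")
    slots = []
    for idx in range(n_chemicals):
        slots.append((idx % n_rows, blocks[idx // n_rows]))
    return bands, slots


def _plate_frame(
    truth: SyntheticTruth,
    plate_id: str,
    rng: np.random.Generator,
    layout: PlateLayout,
    dose: DoseSeries,
    null_wells: bool = False,
) -> pd.DataFrame:
    levels = np.asarray(dose.levels_1x_uM())
    chems = list(truth.chemicals)
    bands, slots = _chemical_slots(layout, levels.size, len(chems))
    scale = rng.uniform(*truth.plate_scale_range)
    base = truth.bval * scale

    rows: list[tuple] = []

    def emit(row: int, col: int, chem: str, conc: float, mode: Mode, tresp: float):
        noise = float(np.exp(rng.normal(0.0, truth.noise_sd))) if truth.noise_sd else 1.0
        raw = max(base * (1.0 + tresp) * noise, 0.0)
        ok = bool(rng.random() >= truth.dropout_rate)
        rows.append((plate_id, row, col, chem, conc, mode.value, raw, ok))

    # control wells follow the layout's designated positions
    for name, positions in layout.control_wells.items():
        for (r, c) in positions:
            mode = layout.band_mode(r) or Mode.NO_MET
            if name == DMSO:
                emit(r, c, DMSO, 0.0, mode, 0.0)
            else:
                resp0, mult = truth.control_truth.get(name, (0.0, 1.0))
                tresp = resp0 * (mult if mode is Mode.MET_POS else 1.0)
                emit(r, c, name, truth.control_conc_uM, mode, tresp)

    # test chemicals: same slot in each mode band
    for chem, ((row_off, cols)) in zip(chems, slots):
        ct = truth.chemicals[chem]
        for (lo, _hi), mode in bands:
            tr = (np.zeros_like(levels) if null_wells
                  else ct.true_resp(levels, mode))
            for conc, col, tresp in zip(levels, cols, tr):
                emit(lo + row_off, col, chem, float(conc), mode, float(tresp))

    return pd.DataFrame(
        rows,
        columns=["plate_id", "row", "col", "chemical_id", "conc", "mode",
                 "raw_lum", "quality_ok"],
    )


def generate_experiment(
    truth: SyntheticTruth,
    n_replicates: int = 4,
    layout: PlateLayout | None = None,
    dose: DoseSeries | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate ``n_replicates`` plates of well-level data plus the truth.

    The same seed always produces identical tables; each plate draws from
    its own stream seeded by (experiment seed, plate index).
    """
    if n_replicates < 1:
        raise PlateConfigError("n_replicates must be >= 1")
    layout = layout or default_layout()
    dose = dose or DoseSeries()
    frames = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([truth.seed % (2**31), rep])
        frames.append(_plate_frame(truth, f"plate{rep + 1:02d}", rng, layout, dose))
    return pd.concat(frames, ignore_index=True), truth


def generate_null_plates(
    truth: SyntheticTruth,
    n_plates: int,
    layout: PlateLayout | None = None,
    dose: DoseSeries | None = None,
) -> pd.DataFrame:
    """Plates whose test wells all have true response 0 (baseline draws);
    used to calibrate the positive-hit rate under the null."""
    layout = layout or default_layout()
    dose = dose or DoseSeries()
    frames = []
    for rep in range(n_plates):
        rng = np.random.default_rng([truth.seed % (2**31), 10_000 + rep])
        frames.append(
            _plate_frame(truth, f"null{rep + 1:03d}", rng, layout, dose,
                         null_wells=True)
        )
    return pd.concat(frames, ignore_index=True)
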