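"""End-to-end orchestration: wells -> normalized -> fits -> shift summary."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import ConcResponseSeries, CurveResult, FitConfig, fit_series
from .normalize import (
    BaselineStats,
    baseline_responses,
    compute_bmad_cutoff,
    normalize,
)
from .plates import DMSO, Mode, WellRecord, default_layout, frame_to_wells
from .shift import (
    ExpectedClass,
    ShiftRecord,
    SummaryCounts,
    auc_of_fit,
    make_shift_record,
    score_concordance,
)


@dataclass(frozen=True)
class ExperimentResult:
    normalized: pd.DataFrame
    baseline: BaselineStats
    curves: list[CurveResult]
    shifts: list[ShiftRecord]
    summary: SummaryCounts | None


def extract_series(
    norm: pd.DataFrame, exclude: set[str] | None = None
) -> list[ConcResponseSeries]:
    """Concentration-response series per test chemical × metabolism mode.

    Controls (the default layout's control names, plus any in ``exclude``)
    are skipped; only dosed wells (conc > 0) in the two microsphere modes
    contribute.
    """
    exclude = {DMSO} | set(default_layout().control_wells) | (exclude or set())
    mask = (
        (~norm["chemical_id"].isin(exclude))
        & (norm["conc"] > 0)
        & (norm["mode"].isin([Mode.MET_NEG.value, Mode.MET_POS.value]))
    )
    out: list[ConcResponseSeries] = []
    sub = norm[mask]
    for (chem, mode), grp in sub.groupby(["chemical_id", "mode"], sort=True):
        out.append(
            ConcResponseSeries(
                chemical_id=str(chem),
                mode=str(mode),
                conc=grp["conc"].to_numpy(float),
                resp=grp["resp"].to_numpy(float),
                replicate_id=grp["plate_id"].to_numpy(),
            )
        )
    return out


def analyze_experiment(
    wells: pd.DataFrame | list[WellRecord],
    expected_classes: dict[str, ExpectedClass] | None = None,
    cfg: FitConfig | None = None,
    control_names: set[str] | None = None,
    auc_grid_points: int = 100,
) -> ExperimentResult:
    """Run the full analysis on well-level data.

    Normalizes per plate, derives the bmad cutoff from the pooled DMSO
    baseline, fits every chemical×mode series, computes per-mode AUC on a
    per-chemical shared log10-concentration grid, and scores ΔAUC
    directions (and concordance when expected classes are given).
    """
    cfg = cfg or FitConfig()
    records = frame_to_wells(wells) if isinstance(wells, pd.DataFrame) else list(wells)
    norm = normalize(records)
    baseline = compute_bmad_cutoff(baseline_responses(norm))
    series = extract_series(norm, exclude=control_names)
    curves = [fit_series(s, baseline, cfg) for s in series]

    by_chem: dict[str, dict[str, CurveResult]] = {}
    for c in curves:
        by_chem.setdefault(c.chemical_id, {})[c.mode] = c

    shifts: list[ShiftRecord] = []
    for chem, modes in sorted(by_chem.items()):
        neg = modes.get(Mode.MET_NEG.value)
        pos = modes.get(Mode.MET_POS.value)
        if neg is None or pos is None or neg.hit_class == "unfit" or pos.hit_class == "unfit":
            continue  # chemicals missing a fit in one mode are excluded
        crange = (
            min(neg.conc_range[0], pos.conc_range[0]),
            max(neg.conc_range[1], pos.conc_range[1]),
        )
        auc_neg = auc_of_fit(neg.winner, crange, auc_grid_points)
        auc_pos = auc_of_fit(pos.winner, crange, auc_grid_points)
        shifts.append(
            make_shift_record(
                chem, auc_neg, auc_pos, neg.hitc, pos.hitc,
                (expected_classes or {}).get(chem),
                threshold=cfg.activity_threshold,
            )
        )
    summary = score_concordance(shifts) if shifts else None
    return ExperimentResult(norm, baseline, curves, shifts, summary)


def _bmd_repr(bmd: float, conc_max: float) -> str:
    if math.isnan(bmd):
        return f">{conc_max:g}"
    return f"{bmd:.4g}"


def curves_to_frame(curves: list[CurveResult]) -> pd.DataFrame:
    """Per-series fit results table (params JSON-encoded in one column)."""
    rows = []
    for c in curves:
        rows.append(
            {
                "chemical_id": c.chemical_id,
                "mode": c.mode,
                "winning_model": c.winner.model_name if c.winner else "NA",
                "params": json.dumps(c.winner.params) if c.winner else "NA",
                "aic": c.winner.aic if c.winner else np.nan,
                "hitc": c.hitc,
                "hit_class": c.hit_class,
                "max_med": c.max_med,
                "bmd": _bmd_repr(c.bmd, c.conc_range[1]) if c.winner else "NA",
                "cutoff": c.cutoff,
                "n_points": c.n_points,
            }
        )
    return pd.DataFrame(rows)


def shifts_to_frame(shifts: list[ShiftRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chemical_id": [s.chemical_id for s in shifts],
            "expected_class": [
                s.expected_class.value if s.expected_class else "NA" for s in shifts
            ],
            "auc_met_neg": [s.auc_neg for s in shifts],
            "auc_met_pos": [s.auc_pos for s in shifts],
            "delta_auc": [s.delta_auc for s in shifts],
            "direction": [s.direction for s in shifts],
            "hitc_met_neg": [s.hitc_neg for s in shifts],
            "hitc_met_pos": [s.hitc_pos for s in shifts],
            "active_any": [s.active_any for s in shifts],
            "active_both": [s.active_both for s in shifts],
            "concordant": [
                "NA" if s.concordant is None else int(s.concordant) for s in shifts
            ],
        }
    )
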