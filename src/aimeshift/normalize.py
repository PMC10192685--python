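"""Normalization to zero-centered fold-change and plate QC metrics.

Raw luminescence is normalized per plate against the median of the
solvent-control (DMSO) wells, the plate baseline ``bval``::

    resp = cval / bval - 1

where ``cval`` is the raw signal after removal of wells flagged low
quality by the liquid handler. The efficacy cutoff is three times the
baseline median absolute deviation (bmad) of the normalized DMSO
responses. Control performance is summarized by the coefficient of
variation (CV%) and the Z'-factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import QCError
from .plates import DMSO, WellRecord, wells_to_frame


@dataclass(frozen=True)
class BaselineStats:
    """Baseline variability and derived efficacy cutoff (cutoff = 3·bmad)."""

    bmad: float
    cutoff: float
    n_baseline_wells: int


@dataclass(frozen=True)
class ControlQC:
    """Per compound×mode control performance. NaN encodes an undefined
    metric (reported as the string "NA")."""

    compound: str
    mode: str
    cv_percent: float
    zprime: float
    n: int


def filter_quality(
    wells: Iterable[WellRecord],
) -> tuple[list[WellRecord], list[WellRecord]]:
    """Partition wells into (kept, dropped) by the liquid-handler flag."""
    kept, dropped = [], []
    for w in wells:
        (kept if w.quality_ok else dropped).append(w)
    return kept, dropped


def compute_bval(wells: Sequence[WellRecord], plate_id: str) -> float:
    """Plate baseline: median raw signal of quality-passing DMSO wells."""
    vals = [
        w.raw_lum
        for w in wells
        if w.plate_id == plate_id and w.chemical_id == DMSO and w.conc == 0 and w.quality_ok
    ]
    if not vals:
        raise QCError(f"plate {plate_id}: no quality-passing DMSO baseline wells")
    bval = float(np.median(vals))
    if bval <= 0:
        raise QCError(f"plate {plate_id}: nonpositive baseline median {bval}")
    return bval


def normalize(wells: Sequence[WellRecord]) -> pd.DataFrame:
    """Normalize kept wells to zero-centered fold-change.

    Returns a DataFrame with the well fields plus ``cval`` (the corrected,
    i.e. quality-filtered, raw signal), the plate ``bval`` and ``resp``.
    Low-quality wells are removed; each plate needs at least one
    quality-passing DMSO well or a :class:`QCError` is raised.
    """
    kept, _dropped = filter_quality(wells)
    if not kept:
        raise QCError("no quality-passing wells to normalize")
    df = wells_to_frame(kept)
    bvals = {pid: compute_bval(kept, pid) for pid in df["plate_id"].unique()}
    df["cval"] = df["raw_lum"]
    df["bval"] = df["plate_id"].map(bvals)
    df["resp"] = df["cval"] / df["bval"] - 1.0
    return df


def baseline_responses(norm: pd.DataFrame) -> np.ndarray:
    """Normalized responses of the DMSO baseline wells (pooled over plates)."""
    mask = (norm["chemical_id"] == DMSO) & (norm["conc"] == 0)
    return norm.loc[mask, "resp"].to_numpy(float)


def compute_bmad_cutoff(baseline_resp: Sequence[float]) -> BaselineStats:
    """Baseline MAD and the 3·bmad efficacy cutoff.

    bmad is the raw median absolute deviation (no normal-consistency
    scaling) of the normalized solvent-control responses.
    """
    x = np.asarray(baseline_resp, float)
    if x.size < 2:
        raise QCError(f"need >= 2 baseline responses, got {x.size}")
    bmad = float(np.median(np.abs(x - np.median(x))))
    return BaselineStats(bmad=bmad, cutoff=3.0 * bmad, n_baseline_wells=int(x.size))


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 · sd / |mean| (sample sd).

    Returns NaN (reported as "NA") when the mean is zero and the metric is
    undefined.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise QCError(f"CV needs >= 2 values, got {x.size}")
    m = float(np.mean(x))
    if m == 0.0:
        return math.nan
    return 100.0 * float(np.std(x, ddof=1)) / abs(m)


def zprime(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Z'-factor screening-quality statistic.

    Z' = 1 − 3(σ_pos + σ_neg)/|µ_pos − µ_neg|; 1 is perfect separation,
    values ≥ 0.5 indicate an excellent assay window. Returns NaN when the
    group means coincide.
    """
    p = np.asarray(pos, float)
    n = np.asarray(neg, float)
    if p.size < 2 or n.size < 2:
        raise QCError("Z' needs >= 2 values per group")
    mp, mn = float(np.mean(p)), float(np.mean(n))
    if mp == mn:
        return math.nan
    sp, sn = float(np.std(p, ddof=1)), float(np.std(n, ddof=1))
    return 1.0 - 3.0 * (sp + sn) / abs(mp - mn)


def control_qc_table(norm: pd.DataFrame, controls: Sequence[str]) -> pd.DataFrame:
    """CV and Z' per control compound × metabolism mode.

    Metrics are computed on zero-centered fold-change values pooled across
    plates (the experimental replicates). The Z' negative group is the
    same-mode DMSO wells; DMSO itself gets a CV computed on 1 + resp
    (fold-change scale, since its resp mean is ~0 by construction) and an
    undefined Z'.
    """
    rows: list[ControlQC] = []
    for compound in controls:
        sub = norm[norm["chemical_id"] == compound]
        for mode in sorted(sub["mode"].unique()):
            vals = sub.loc[sub["mode"] == mode, "resp"].to_numpy(float)
            if vals.size < 2:
                continue
            if compound == DMSO:
                cv_val = cv(1.0 + vals)
                z_val = math.nan
            else:
                cv_val = cv(vals)
                negmask = (
                    (norm["chemical_id"] == DMSO)
                    & (norm["conc"] == 0)
                    & (norm["mode"] == mode)
                )
                neg = norm.loc[negmask, "resp"].to_numpy(float)
                z_val = zprime(vals, neg) if neg.size >= 2 else math.nan
            rows.append(ControlQC(compound, mode, cv_val, z_val, int(vals.size)))
    df = pd.DataFrame(
        {
            "compound": [r.compound for r in rows],
            "metabolism": [r.mode for r in rows],
            "CV": [round(r.cv_percent, 2) if math.isfinite(r.cv_percent) else "NA" for r in rows],
            "Z-factor": [round(r.zprime, 2) if math.isfinite(r.zprime) else "NA" for r in rows],
            "n": [r.n for r in rows],
        }
    )
    return df
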