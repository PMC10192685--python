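"""ΔAUC metabolism-shift statistic, direction calls, and concordance.

For each chemical the winning fitted curve in each metabolism mode is
integrated (trapezoidal rule) over a shared log10-concentration grid.
ΔAUC = AUC(Met Pos) − AUC(Met Neg): a negative value means metabolism
destroyed estrogenic activity (bioinactivation), positive means
metabolism created it (bioactivation), exactly zero (two constant
winners) means no change. Concordance scores observed directions against
expected classifications from prior metabolism-retrofit screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .fitting import ModelFit


class ExpectedClass(str, Enum):
    AGONIST = "Agonist"
    AGONIST_NEGATIVE = "Agonist Negative"
    BIOACTIVATED = "Bioactivated"
    BIOINACTIVATED = "Bioinactivated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DIRECTIONS = ("inactivated", "no_change", "activated")


@dataclass(frozen=True)
class ShiftRecord:
    """Per-chemical metabolism-shift summary."""

    chemical_id: str
    auc_neg: float
    auc_pos: float
    delta_auc: float
    direction: str                  # inactivated / no_change / activated
    hitc_neg: float
    hitc_pos: float
    active_any: bool
    active_both: bool
    expected_class: ExpectedClass | None = None
    concordant: bool | None = None  # None when no rule applies


@dataclass(frozen=True)
class SummaryCounts:
    """Screen-level tallies mirroring the published summary statistics."""

    n_tested: int
    n_active_any: int
    n_active_both: int
    n_shift_screened: int           # expected Bioactivated/Bioinactivated
    n_shift_active: int             # of those, active in >= 1 mode
    n_concordant_overall: int       # concordant among shift-active
    n_bioactivated_active: int
    n_concordant_bioactivated: int
    n_bioinactivated_active: int
    n_concordant_bioinactivated: int
    n_delta_positive: int           # activated among shift-active
    n_delta_negative: int
    n_no_change: int
    n_concordant_rows: int          # concordance flags over all chemicals

    def __post_init__(self) -> None:
        assert self.n_delta_positive + self.n_delta_negative + self.n_no_change \
            == self.n_shift_active, "direction tallies must partition shift-active"
        assert self.n_shift_active <= self.n_shift_screened <= self.n_tested
        assert self.n_active_both <= self.n_active_any <= self.n_tested
        assert self.n_concordant_overall == (
            self.n_concordant_bioactivated + self.n_concordant_bioinactivated
        )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["pct_active_any"] = _pct(self.n_active_any, self.n_tested)
        d["pct_concordant_overall"] = _pct(self.n_concordant_overall, self.n_shift_active)
        d["pct_concordant_bioactivated"] = _pct(
            self.n_concordant_bioactivated, self.n_bioactivated_active)
        d["pct_concordant_bioinactivated"] = _pct(
            self.n_concordant_bioinactivated, self.n_bioinactivated_active)
        return d


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else math.nan


def auc_of_fit(
    winner: ModelFit | None,
    conc_range: tuple[float, float],
    grid_points: int = 100,
) -> float:
    """Trapezoidal AUC of the fitted curve on a log10-concentration grid.

    The integrand is the predicted zero-centered fold-change as a function
    of log10 concentration, so the AUC carries units of fold-change ×
    log10(µM). A constant winner integrates to exactly 0.
    """
    lo, hi = conc_range
    if not (lo < hi) or grid_points < 2:
        raise ValueError(f"bad AUC grid: range {conc_range}, {grid_points} points")
    if winner is None or winner.model_name == "constant":
        return 0.0
    u = np.linspace(np.log10(lo), np.log10(hi), grid_points)
    y = winner.predict(10.0 ** u)
    return float(np.trapezoid(y, u))


def classify_shift(auc_neg: float, auc_pos: float) -> tuple[float, str]:
    """ΔAUC and its strict-sign direction call.

    Exact zero (both modes fit constant) is "no_change"; any nonzero
    difference is directional.
    """
    if not (math.isfinite(auc_neg) and math.isfinite(auc_pos)):
        raise ValueError("AUCs must be finite")
    delta = auc_pos - auc_neg
    if delta < 0:
        return delta, "inactivated"
    if delta > 0:
        return delta, "activated"
    return 0.0, "no_change"


def concordance_rule(
    expected: ExpectedClass, direction: str, hitc_neg: float, hitc_pos: float,
    threshold: float = 0.9,
) -> bool | None:
    """Is the observed outcome concordant with the expected classification?

    Directional classes compare the ΔAUC sign; Agonist expects activity in
    both modes; Agonist Negative expects either no Met-Neg activity or a
    metabolic loss of activity. Returns None when no rule applies.
    """
    pos_neg = hitc_neg >= threshold
    pos_pos = hitc_pos >= threshold
    if expected is ExpectedClass.BIOACTIVATED:
        return direction == "activated"
    if expected is ExpectedClass.BIOINACTIVATED:
        return direction == "inactivated"
    if expected is ExpectedClass.AGONIST:
        return pos_neg and pos_pos
    if expected is ExpectedClass.AGONIST_NEGATIVE:
        return (not pos_neg) or direction == "inactivated"
    return None


def make_shift_record(
    chemical_id: str,
    auc_neg: float,
    auc_pos: float,
    hitc_neg: float,
    hitc_pos: float,
    expected_class: ExpectedClass | None = None,
    threshold: float = 0.9,
) -> ShiftRecord:
    delta, direction = classify_shift(auc_neg, auc_pos)
    active_any = (hitc_neg >= threshold) or (hitc_pos >= threshold)
    active_both = (hitc_neg >= threshold) and (hitc_pos >= threshold)
    concordant = None
    if expected_class is not None:
        concordant = concordance_rule(
            expected_class, direction, hitc_neg, hitc_pos, threshold)
    return ShiftRecord(chemical_id, auc_neg, auc_pos, delta, direction,
                       hitc_neg, hitc_pos, active_any, active_both,
                       expected_class, concordant)


def score_concordance(records: Sequence[ShiftRecord]) -> SummaryCounts:
    """Screen-level summary counts.

    Shift concordance is evaluated only on chemicals that are active in at
    least one mode and expected Bioactivated or Bioinactivated; the
    row-level concordance tally additionally counts the agonist classes.
    """
    shift_classes = (ExpectedClass.BIOACTIVATED, ExpectedClass.BIOINACTIVATED)
    shift_screened = [r for r in records if r.expected_class in shift_classes]
    shift_active = [r for r in shift_screened if r.active_any]
    bio_act = [r for r in shift_active if r.expected_class is ExpectedClass.BIOACTIVATED]
    bio_inact = [r for r in shift_active if r.expected_class is ExpectedClass.BIOINACTIVATED]
    return SummaryCounts(
        n_tested=len(records),
        n_active_any=sum(r.active_any for r in records),
        n_active_both=sum(r.active_both for r in records),
        n_shift_screened=len(shift_screened),
        n_shift_active=len(shift_active),
        n_concordant_overall=sum(bool(r.concordant) for r in shift_active),
        n_bioactivated_active=len(bio_act),
        n_concordant_bioactivated=sum(bool(r.concordant) for r in bio_act),
        n_bioinactivated_active=len(bio_inact),
        n_concordant_bioinactivated=sum(bool(r.concordant) for r in bio_inact),
        n_delta_positive=sum(r.direction == "activated" for r in shift_active),
        n_delta_negative=sum(r.direction == "inactivated" for r in shift_active),
        n_no_change=sum(r.direction == "no_change" for r in shift_active),
        n_concordant_rows=sum(bool(r.concordant) for r in records),
    )


def rank_by_delta(records: Iterable[ShiftRecord]) -> list[ShiftRecord]:
    """Active chemicals stably sorted by ascending ΔAUC (the rank-order
    view of metabolism-dependent bioactivity)."""
    active = [r for r in records if r.active_any]
    return sorted(active, key=lambda r: r.delta_auc)
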