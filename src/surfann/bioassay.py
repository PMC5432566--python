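"""Bioassay statistics: residual rate, MIC calling, inhibition-zone grading.

The antimicrobial readout is the diameter of the inhibition zone (DAC, mm)
in a plate-diffusion assay. Stability experiments compare a treated
preparation against a time-matched fresh control:

    residual rate (%) = 100 * DAC(treated) / DAC(control)

MIC is read from a two-fold broth-dilution series as the lowest
concentration at or above which no well shows growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from .exceptions import AlignmentError, DomainError, QualityControlError

GRADES = ("-", "+", "++", "+++")
DEFAULT_GRADE_THRESHOLDS = (10.0, 20.0, 30.0)


def residual_rate(dac_experimental: float, dac_control: float) -> float:
    """Percent activity retained: 100 * experimental / control (may exceed 100)."""
    if dac_control <= 0:
        raise DomainError(f"dac_control must be positive, got {dac_control}")
    if dac_experimental < 0:
        raise DomainError(f"dac_experimental must be non-negative, got {dac_experimental}")
    return 100.0 * dac_experimental / dac_control


def grade_dac(dac_mm: float, thresholds: Sequence[float] = DEFAULT_GRADE_THRESHOLDS) -> str:
    """Grade an inhibition zone into -, +, ++, +++ by left-closed bins.

    With the default cut-offs (10, 20, 30 mm) a zone of 30 mm or more —
    "more than 3 cm" — earns the top grade.
    """
    if dac_mm < 0:
        raise DomainError(f"dac_mm must be non-negative, got {dac_mm}")
    t = tuple(thresholds)
    if len(t) != 3 or not (t[0] < t[1] < t[2]):
        raise DomainError(f"thresholds must be 3 strictly ascending cut-offs, got {t}")
    grade = GRADES[0]
    for cut, g in zip(t, GRADES[1:]):
        if dac_mm >= cut:
            grade = g
    return grade


@dataclass(frozen=True)
class DilutionSeries:
    """A two-fold dilution readout: (concentration, growth) rows plus controls.

    ``rows`` must be ordered by strictly descending positive concentration
    (sort first if needed); ``controls`` maps blank/negative/positive to the
    observed growth call.
    """

    rows: tuple[tuple[float, bool], ...]
    controls: Mapping[str, bool] = field(
        default_factory=lambda: {"blank": False, "negative": False, "positive": True}
    )

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.rows]
        if any(c <= 0 for c in concs):
            raise DomainError("concentrations must be positive")
        if list(concs) != sorted(concs, reverse=True) or len(set(concs)) != len(concs):
            raise DomainError("concentrations must be strictly descending")


class MicResult(NamedTuple):
    """MIC call: concentration (None when not reached) plus a monotonicity flag."""

    mic: float | None
    reached: bool
    monotone: bool


def mic_from_dilution(series: DilutionSeries) -> MicResult:
    """Lowest concentration at or above which every row shows no growth.

    The positive control must grow and the negative control must not,
    otherwise a :class:`QualityControlError` names the failed control. A
    growth reading above a no-growth reading (non-monotone pattern) does not
    change the call but is flagged.
    """
    controls = series.controls
    if not controls.get("positive", False):
        raise QualityControlError("positive", "positive control shows no growth")
    if controls.get("negative", False):
        raise QualityControlError("negative", "negative control shows growth")
    rows = series.rows
    if not rows:
        raise DomainError("dilution series has no rows")
    if rows[0][1]:
        return MicResult(None, False, _is_monotone(rows))
    mic = rows[0][0]
    for conc, growth in rows[1:]:
        if growth:
            break
        mic = conc
    return MicResult(mic, True, _is_monotone(rows))


def _is_monotone(rows: Sequence[tuple[float, bool]]) -> bool:
    # Monotone: once growth appears (going down in concentration) it persists.
    seen_no_growth_below_growth = False
    seen_growth = False
    for _, growth in rows:  # descending concentration
        if growth:
            seen_growth = True
        elif seen_growth:
            seen_no_growth_below_growth = True
    return not seen_no_growth_below_growth


def summarize_stability(
    table: pd.DataFrame, control_condition: str = "control"
) -> pd.DataFrame:
    """Per-condition residual-rate trajectories from a tidy DAC table.

    Input columns: condition, time, dac_mm (replicate optional). Each row's
    residual rate is computed against the mean control DAC at the same time
    point; output is tidy with columns (condition, time, mean_pct, sd_pct, n).
    Missing time-matched controls raise :class:`AlignmentError` listing the
    orphan (condition, time) pairs.
    """
    required = {"condition", "time", "dac_mm"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"stability table missing columns {sorted(missing)}")
    ctrl = table[table["condition"] == control_condition]
    if ctrl.empty:
        raise AlignmentError(f"control condition {control_condition!r} absent from table")
    ctrl_mean = ctrl.groupby("time")["dac_mm"].mean()
    exp = table[table["condition"] != control_condition]
    orphans = sorted(
        {
            (row.condition, row.time)
            for row in exp.itertuples()
            if row.time not in ctrl_mean.index
        }
    )
    if orphans:
        raise AlignmentError(
            f"no time-matched control for {len(orphans)} (condition, time) pair(s): "
            f"{orphans[:5]}",
            orphans=orphans,
        )
    rates = exp.assign(
        pct=[
            residual_rate(row.dac_mm, ctrl_mean[row.time]) for row in exp.itertuples()
        ]
    )
    out = (
        rates.groupby(["condition", "time"])["pct"]
        .agg(mean_pct="mean", sd_pct=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
        .reset_index()
        .sort_values(["condition", "time"], ignore_index=True)
    )
    return out
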