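"""Dose-response-curve statistics and time-window selection.

The toxicity effect (TE) of a chemical at concentration rank k and time t
is the percentage deviation of the treated curve from the negative control,
either pointwise or through the area under the curve from treatment to t.
The 11-element TE vector across concentrations at a fixed time is the DRC
profile; classifying on DRC profiles time point by time point yields an
SR-versus-time series from which a favourable time window can be selected
and used to restrict the raw curves before featurization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .errors import EmptyInputError, GridError, RangeError, ShapeError
from .evaluation import SplitPlan, repeated_split_evaluation
from .preprocess import TCRC, TCRCSet

_GRID_ATOL = 1e-9


@dataclass(frozen=True)
class DRCProfile:
    """Toxicity effect across the 11 concentrations at one time point."""

    time: float
    te_values: np.ndarray  # percent, highest concentration first
    variant: str  # "point" | "auc"
    chemical_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "te_values", np.asarray(self.te_values, dtype=float))
        if self.te_values.size != 11:
            raise ShapeError(f"a DRC profile holds 11 values, got {self.te_values.size}")


@dataclass(frozen=True)
class TimeInterval:
    """Inclusive time window in hours, with the SR threshold that chose it."""

    start: float
    end: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise RangeError(f"need start < end, got [{self.start}, {self.end}]")


def _grid_index(times: np.ndarray, t: float) -> int:
    hits = np.nonzero(np.abs(times - t) <= _GRID_ATOL)[0]
    if hits.size == 0:
        raise GridError(f"time {t} h is not on the sampling grid")
    return int(hits[0])


def _rank_curve(tcrc_set: TCRCSet, k: int) -> TCRC:
    if not 1 <= k <= len(tcrc_set.curves):
        raise RangeError(f"concentration rank must be in 1..{len(tcrc_set.curves)}, got {k}")
    return tcrc_set.curves[k - 1]


def toxicity_effect_point(tcrc_set: TCRCSet, t: float, k: int) -> float:
    """Pointwise TE (%) of the rank-k curve at hour t relative to the NC."""
    curve = _rank_curve(tcrc_set, k)
    nc = tcrc_set.negative_control
    i = _grid_index(curve.times, t)
    nc_value = nc.nci[i]
    if nc_value == 0:
        raise ZeroDivisionError(f"negative control is 0 at t={t} h")
    return 100.0 * (curve.nci[i] - nc_value) / nc_value


def toxicity_effect_auc(tcrc_set: TCRCSet, t: float, k: int) -> float:
    """AUC-based TE (%): relative excess area under the treated curve.

    Areas run from the start of the grid to hour t by the composite
    trapezoid rule.
    """
    curve = _rank_curve(tcrc_set, k)
    nc = tcrc_set.negative_control
    i = _grid_index(curve.times, t)
    if i == 0:
        raise RangeError("AUC-based TE needs t strictly after the grid start")
    x = curve.times[: i + 1]
    auc_curve = np.trapezoid(curve.nci[: i + 1], x)
    auc_nc = np.trapezoid(nc.nci[: i + 1], x)
    if auc_nc == 0:
        raise ZeroDivisionError(f"negative-control AUC is 0 up to t={t} h")
    return 100.0 * (auc_curve - auc_nc) / auc_nc


def drc_at_time(tcrc_set: TCRCSet, t: float, variant: str = "point") -> DRCProfile:
    """The 11-value TE profile of one chemical at hour t."""
    if variant == "point":
        te = [toxicity_effect_point(tcrc_set, t, k) for k in range(1, 12)]
    elif variant == "auc":
        te = [toxicity_effect_auc(tcrc_set, t, k) for k in range(1, 12)]
    else:
        raise RangeError(f"variant must be 'point' or 'auc', got {variant!r}")
    return DRCProfile(time=t, te_values=np.array(te), variant=variant,
                      chemical_id=tcrc_set.chemical_id)


def drc_matrix(
    tcrc_sets: Sequence[TCRCSet], t: float, variant: str = "point"
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-chemical DRC profiles at hour t into (X, labels)."""
    if not tcrc_sets:
        raise EmptyInputError("no TCRC sets")
    rows = [drc_at_time(s, t, variant).te_values for s in tcrc_sets]
    labels = np.array([s.label if s.label is not None else "" for s in tcrc_sets])
    return np.vstack(rows), labels


def sr_time_profile(
    tcrc_sets: Sequence[TCRCSet],
    factory: Callable[[np.ndarray, np.ndarray, int], object],
    times: Sequence[float],
    plan: SplitPlan | None = None,
    variant: str = "point",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean repeated-split SR of a DRC-profile classifier at each time.

    The same split plan is reused across times so the series reflects the
    information content of each time point, not sampling noise. Returns
    ``(times, mean_sr)`` arrays aligned elementwise.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise EmptyInputError("no time points")
    labels = np.array([s.label for s in tcrc_sets])
    if plan is None:
        plan = SplitPlan.from_labels(labels, seed=seed)
    mean_sr = np.empty(times.size)
    for j, t in enumerate(times):
        features, _ = drc_matrix(tcrc_sets, t, variant)
        result = repeated_split_evaluation(
            features, labels, factory, plan=plan, task=f"drc@{t:g}h"
        )
        mean_sr[j] = result.mean_sr
    return times, mean_sr


def select_time_interval(
    times: Sequence[float],
    sr_values: Sequence[float],
    threshold: float | None = None,
) -> TimeInterval | None:
    """Longest contiguous run of times whose SR reaches the threshold.

    The default threshold is the profile mean. Returns ``None`` when no
    time qualifies (callers fall back to the full window).
    """
    times = np.asarray(times, dtype=float)
    sr_values = np.asarray(sr_values, dtype=float)
    if times.size == 0:
        raise EmptyInputError("empty SR profile")
    if times.shape != sr_values.shape:
        raise ShapeError("times and SR values must align")
    if threshold is None:
        threshold = float(np.mean(sr_values))
    above = sr_values >= threshold
    best_start, best_length = None, 0
    run_start = None
    for i, ok in enumerate([*above, False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start > best_length:
                best_start, best_length = run_start, i - run_start
            run_start = None
    if best_start is None or best_length < 2:
        # a single qualifying point has zero width; treat as empty selection
        return None
    return TimeInterval(
        start=float(times[best_start]),
        end=float(times[best_start + best_length - 1]),
        threshold=threshold,
    )


def restrict_tcrc(tcrc_set: TCRCSet, interval: TimeInterval) -> TCRCSet:
    """Truncate every curve of a set to the inclusive time window."""
    grid = tcrc_set.times
    if interval.start < grid[0] - _GRID_ATOL or interval.end > grid[-1] + _GRID_ATOL:
        raise RangeError(
            f"interval [{interval.start}, {interval.end}] outside grid "
            f"[{grid[0]}, {grid[-1]}]"
        )
    mask = (grid >= interval.start - _GRID_ATOL) & (grid <= interval.end + _GRID_ATOL)

    def cut(curve: TCRC) -> TCRC:
        return TCRC(
            times=curve.times[mask],
            nci=curve.nci[mask],
            concentration=curve.concentration,
            chemical_id=curve.chemical_id,
        )

    return replace(
        tcrc_set,
        curves=[cut(c) for c in tcrc_set.curves],
        negative_control=cut(tcrc_set.negative_control),
    )
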