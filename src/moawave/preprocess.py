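"""Normalization and resampling of raw cell-index recordings.

Raw impedance (or instrument-exported cell-index) well traces are turned
into time-concentration response curves (TCRCs): the cell index is
normalized to its value just before chemical treatment and resampled by a
cubic spline onto a uniform hourly grid covering the post-treatment window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    EmptyInputError,
    ExtrapolationError,
    InsufficientDataError,
    InvalidBackgroundError,
    NonPositiveReferenceError,
    ShapeError,
)

#: Default post-treatment window: hours 0..72 inclusive, 73 samples.
DEFAULT_GRID = np.arange(0.0, 73.0, 1.0)

#: Sentinel concentration for negative-control curves.
NEGATIVE_CONTROL = None

#: Number of test concentrations per chemical (1:3 serial dilution design).
N_CONCENTRATIONS = 11

_GRID_ATOL = 1e-9
# the spline-resampled value at t = 0 sits near, not exactly at, the
# pre-treatment reference sample, so the anchor check needs slack
_ANCHOR_ATOL = 0.05


@dataclass(frozen=True)
class ImpedanceRecord:
    """One impedance measurement across frequencies for a single well.

    ``r_cell`` is the electrode impedance with cells present, ``r_b`` the
    background impedance of the same well without cells, both in ohms and
    indexed by measurement frequency.
    """

    well_id: str
    frequencies: np.ndarray
    r_cell: np.ndarray
    r_b: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, dtype=float))
        object.__setattr__(self, "r_cell", np.asarray(self.r_cell, dtype=float))
        object.__setattr__(self, "r_b", np.asarray(self.r_b, dtype=float))
        if self.r_cell.size == 0:
            raise EmptyInputError("impedance record has no frequencies")
        if not (self.r_cell.shape == self.r_b.shape == self.frequencies.shape):
            raise ShapeError(
                f"frequency/impedance lengths differ: {self.frequencies.shape}, "
                f"{self.r_cell.shape}, {self.r_b.shape}"
            )
        if np.any(self.r_b <= 0):
            raise InvalidBackgroundError("background impedance must be > 0 at every frequency")


@dataclass(frozen=True)
class CellIndexSeries:
    """Cell-index trace for one well; index 0 is the point right before treatment."""

    times: np.ndarray  # hours relative to treatment; strictly increasing
    values: np.ndarray  # dimensionless CI

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.size == 0:
            raise EmptyInputError("empty cell-index series")
        if self.times.shape != self.values.shape:
            raise ShapeError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ShapeError("times must be strictly increasing")

    @property
    def treatment_index(self) -> int:
        """Index of the sample right before (or at) treatment time t = 0.

        Traces that start after treatment fall back to their first sample.
        """
        at_or_before = np.nonzero(self.times <= 0.0)[0]
        return int(at_or_before[-1]) if at_or_before.size else 0


@dataclass(frozen=True)
class TCRC:
    """Normalized response curve of one well on a uniform hourly grid."""

    times: np.ndarray
    nci: np.ndarray
    concentration: float | None  # None marks the negative control
    chemical_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "nci", np.asarray(self.nci, dtype=float))
        if self.times.size == 0:
            raise EmptyInputError("empty TCRC")
        if self.times.shape != self.nci.shape:
            raise ShapeError("times and nci must have equal length")

    @property
    def is_negative_control(self) -> bool:
        return self.concentration is None

    def validate(self, require_anchor: bool = True) -> None:
        """Check the hourly-grid invariants.

        ``require_anchor`` additionally asserts that the curve starts at the
        treatment time with NCI == 1; curves truncated to a later window
        (see :func:`moawave.drc.restrict_tcrc`) skip that check.
        """
        steps = np.diff(self.times)
        if self.times.size < 2 or not np.allclose(steps, 1.0, atol=_GRID_ATOL):
            raise ShapeError("TCRC grid spacing must be exactly 1 h")
        if require_anchor:
            if abs(self.times[0]) > _GRID_ATOL:
                raise ShapeError("TCRC must start at the treatment time (t = 0)")
            if abs(self.nci[0] - 1.0) > _ANCHOR_ATOL:
                raise ShapeError("NCI at treatment time must equal 1")


@dataclass
class TCRCSet:
    """All response curves of one chemical: 11 concentrations plus negative control.

    ``curves`` are ordered from the highest concentration (rank 1) to the
    lowest (rank 11); ``label`` carries the MOA cluster when known.
    """

    chemical_id: str
    curves: list[TCRC]
    negative_control: TCRC
    label: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.curves[0].times

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c.concentration for c in self.curves], dtype=float)

    def validate(self, require_anchor: bool = True, dilution_rtol: float = 0.25) -> None:
        if len(self.curves) != N_CONCENTRATIONS:
            raise ShapeError(
                f"expected {N_CONCENTRATIONS} concentration curves, got {len(self.curves)}"
            )
        ref = self.curves[0].times
        for curve in [*self.curves, self.negative_control]:
            curve.validate(require_anchor=require_anchor)
            if curve.times.shape != ref.shape or not np.allclose(curve.times, ref, atol=_GRID_ATOL):
                raise ShapeError("all curves of a set must share one time grid")
        conc = self.concentrations
        if np.any(np.isnan(conc)) or np.any(np.diff(conc) >= 0):
            raise ShapeError("concentrations must be strictly decreasing (highest first)")
        ratios = conc[:-1] / conc[1:]
        if np.any(np.abs(ratios - 3.0) > dilution_rtol * 3.0):
            raise ShapeError("neighbouring concentrations must follow a ~1:3 serial dilution")
        if not self.negative_control.is_negative_control:
            raise ShapeError("negative_control curve must carry the control sentinel")


def compute_cell_index(record: ImpedanceRecord) -> float:
    """Convert one impedance measurement to a cell-index value.

    CI is the maximum, over measurement frequencies, of the relative
    impedance change ``r_cell/r_b - 1``; it is 0 when no cells are present
    and never drops below -1.
    """
    return float(np.max(record.r_cell / record.r_b - 1.0))


def normalize_ci(series: CellIndexSeries) -> CellIndexSeries:
    """Divide a CI trace by its value right before treatment."""
    ref = series.values[series.treatment_index]
    if ref <= 0:
        raise NonPositiveReferenceError(
            f"CI at the pre-treatment point must be > 0, got {ref!r}"
        )
    return CellIndexSeries(times=series.times, values=series.values / ref)


def resample_uniform(
    times: np.ndarray,
    values: np.ndarray,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Interpolate an irregularly sampled trace onto the hourly grid.

    Uses a not-a-knot cubic spline, which passes through every input sample
    and reproduces cubic polynomials exactly. The grid must lie inside the
    observed span; extrapolation is refused.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ShapeError("times and values must have equal length")
    if times.size < 4:
        raise InsufficientDataError(
            f"cubic spline resampling needs >= 4 points, got {times.size}"
        )
    if np.any(np.diff(times) <= 0):
        raise ShapeError("times must be strictly increasing")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid[0] < times[0] - _GRID_ATOL or grid[-1] > times[-1] + _GRID_ATOL:
        raise ExtrapolationError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond data span "
            f"[{times[0]}, {times[-1]}]"
        )
    spline = CubicSpline(times, values, bc_type="not-a-knot")
    out = spline(grid)
    # contract: grid nodes coinciding with input times reproduce the input
    # exactly (the spline itself leaves ~1 ulp at the right endpoint)
    hits = np.searchsorted(times, grid)
    for j, i in enumerate(hits):
        for candidate in (i - 1, i):
            if 0 <= candidate < times.size and abs(times[candidate] - grid[j]) <= _GRID_ATOL:
                out[j] = values[candidate]
    return out


def make_tcrc(
    series: CellIndexSeries,
    concentration: float | None,
    chemical_id: str = "",
    grid: np.ndarray | None = None,
) -> TCRC:
    """Normalize one CI trace and resample it onto the hourly grid.

    Pre-treatment samples (t < 0) are used as spline support but only the
    post-treatment grid is kept.
    """
    normalized = normalize_ci(series)
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    nci = resample_uniform(normalized.times, normalized.values, grid)
    return TCRC(times=grid, nci=nci, concentration=concentration, chemical_id=chemical_id)
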