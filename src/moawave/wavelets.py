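"""Wavelet featurization of concatenated response curves.

The classifier input is built in three steps: the curves of one chemical
are concatenated in concentration-rank order (optionally followed by the
negative control), the resulting vector is decomposed by a multilevel
discrete wavelet transform, and the coefficient blocks are pruned
coarse-to-fine.

The transform is the order-2 Daubechies filter bank with half-point
symmetric boundary extension, matching the classic MATLAB ``wavedec``
convention: each level maps a block of length ``L`` to approximation and
detail blocks of length ``floor((L + 3) / 2)``, and the full coefficient
set reconstructs the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, RangeError, ShapeError
from .preprocess import TCRCSet

# Order-2 Daubechies filter bank. rec_lo is the scaling filter; the
# decomposition filters are its reverse and quadrature mirror.
_S3 = np.sqrt(3.0)
_D = 4.0 * np.sqrt(2.0)
REC_LO = np.array([(1 + _S3) / _D, (3 + _S3) / _D, (3 - _S3) / _D, (1 - _S3) / _D])
DEC_LO = REC_LO[::-1].copy()
DEC_HI = np.array([-REC_LO[0], REC_LO[1], -REC_LO[2], REC_LO[3]])
REC_HI = DEC_HI[::-1].copy()
FILTER_LENGTH = 4


@dataclass(frozen=True)
class ConcatenatedInput:
    """Raw classifier input: curves joined end-to-end in rank order."""

    values: np.ndarray
    n_concentrations: int
    include_nc: bool
    segment_lengths: tuple[int, ...]

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class WaveletDecomposition:
    """Coefficient blocks of an n-level decomposition, coarse to fine.

    ``details[0]`` is the coarsest detail block (level n) and
    ``details[-1]`` the finest (level 1).
    """

    level: int
    approx: np.ndarray
    details: tuple[np.ndarray, ...]
    input_length: int

    @property
    def blocks(self) -> tuple[np.ndarray, ...]:
        return (self.approx, *self.details)

    @property
    def block_lengths(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)

    @property
    def n_coefficients(self) -> int:
        return sum(self.block_lengths)


@dataclass(frozen=True)
class FeatureVector:
    """Classifier input vector with its provenance recorded."""

    values: np.ndarray
    provenance: str  # "raw" or "W{n}({m})"
    n_concentrations: int | None = None
    include_nc: bool | None = None
    level: int | None = None
    kept_blocks: int | None = None

    def __len__(self) -> int:
        return int(self.values.size)


def block_length(length: int) -> int:
    """Output block length of one decomposition step for an input of ``length``."""
    return (length + FILTER_LENGTH - 1) // 2


def coefficient_counts(input_length: int, level: int) -> tuple[int, ...]:
    """Block lengths (CA_n, CD_n, ..., CD_1) without computing any transform."""
    if level < 1:
        raise RangeError(f"level must be >= 1, got {level}")
    lengths = []
    current = input_length
    for _ in range(level):
        current = block_length(current)
        lengths.append(current)
    # coarse to fine: CA_n, CD_n, CD_{n-1}, ..., CD_1
    return (lengths[-1], *lengths[::-1])


def concatenate_tcrc(tcrc_set: TCRCSet, n: int, include_nc: bool = True) -> ConcatenatedInput:
    """Join the ``n`` highest-concentration curves (rank order), then the NC.

    The first segment is always the rank-1 (highest concentration) curve.
    """
    if not 1 <= n <= len(tcrc_set.curves):
        raise RangeError(f"n must be in 1..{len(tcrc_set.curves)}, got {n}")
    segments = [curve.nci for curve in tcrc_set.curves[:n]]
    if include_nc:
        segments.append(tcrc_set.negative_control.nci)
    return ConcatenatedInput(
        values=np.concatenate(segments),
        n_concentrations=n,
        include_nc=include_nc,
        segment_lengths=tuple(len(s) for s in segments),
    )


def _dwt_single(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ext = np.pad(x, (FILTER_LENGTH - 1, FILTER_LENGTH - 1), mode="symmetric")
    approx = np.convolve(ext, DEC_LO, mode="valid")[1::2]
    detail = np.convolve(ext, DEC_HI, mode="valid")[1::2]
    return approx, detail


def _idwt_single(approx: np.ndarray, detail: np.ndarray, out_length: int) -> np.ndarray:
    def upconv(coeffs: np.ndarray, filt: np.ndarray) -> np.ndarray:
        upsampled = np.zeros(2 * coeffs.size - 1)
        upsampled[::2] = coeffs
        full = np.convolve(upsampled, filt, mode="full")
        first = (full.size - out_length) // 2
        return full[first:first + out_length]

    return upconv(approx, REC_LO) + upconv(detail, REC_HI)


def dwt_decompose(signal: np.ndarray, level: int = 5) -> WaveletDecomposition:
    """Multilevel discrete wavelet decomposition of a 1-D signal.

    The approximation block is split recursively ``level`` times; detail
    blocks are returned coarse-to-fine.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size == 0:
        raise EmptyInputError("cannot decompose an empty signal")
    if level < 1:
        raise RangeError(f"level must be >= 1, got {level}")
    approx = signal
    details: list[np.ndarray] = []
    for _ in range(level):
        approx, detail = _dwt_single(approx)
        details.append(detail)
    return WaveletDecomposition(
        level=level,
        approx=approx,
        details=tuple(details[::-1]),
        input_length=signal.size,
    )


def dwt_reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`dwt_decompose`; exact up to floating-point roundoff."""
    lengths = [dec.input_length]
    for _ in range(dec.level - 1):
        lengths.append(block_length(lengths[-1]))
    approx = dec.approx
    for detail, out_length in zip(dec.details, lengths[::-1]):
        approx = _idwt_single(approx, detail, out_length)
    return approx


def select_coefficients(dec: WaveletDecomposition, m: int) -> FeatureVector:
    """Keep the ``m`` coarsest coefficient blocks.

    ``m = 1`` keeps only the approximation block; ``m = level + 1`` keeps
    everything. The result for ``m`` is always a prefix of the result for
    ``m + 1``.
    """
    if not 1 <= m <= dec.level + 1:
        raise RangeError(f"m must be in 1..{dec.level + 1}, got {m}")
    return FeatureVector(
        values=np.concatenate(dec.blocks[:m]),
        provenance=f"W{dec.level}({m})",
        level=dec.level,
        kept_blocks=m,
    )


def reduction_percent(feature: FeatureVector | int, raw_length: int) -> int:
    """Data reduction of a pruned feature vector vs the raw input, in whole %."""
    if raw_length <= 0:
        raise RangeError(f"raw_length must be > 0, got {raw_length}")
    n = feature if isinstance(feature, int) else len(feature)
    return int(round(100.0 * (1.0 - n / raw_length)))


def featurize(
    tcrc_set: TCRCSet,
    n_concentrations: int = 11,
    include_nc: bool = True,
    level: int = 5,
    kept_blocks: int | None = 4,
) -> FeatureVector:
    """Full featurization of one chemical.

    ``kept_blocks=None`` skips the wavelet transform and returns the raw
    concatenation. The defaults are the W_5(4) operating point on all 11
    concentrations plus negative control.
    """
    concatenated = concatenate_tcrc(tcrc_set, n_concentrations, include_nc)
    if kept_blocks is None:
        return FeatureVector(
            values=concatenated.values,
            provenance="raw",
            n_concentrations=n_concentrations,
            include_nc=include_nc,
        )
    dec = dwt_decompose(concatenated.values, level)
    selected = select_coefficients(dec, kept_blocks)
    return FeatureVector(
        values=selected.values,
        provenance=selected.provenance,
        n_concentrations=n_concentrations,
        include_nc=include_nc,
        level=level,
        kept_blocks=kept_blocks,
    )


def feature_matrix(
    tcrc_sets: list[TCRCSet],
    n_concentrations: int = 11,
    include_nc: bool = True,
    level: int = 5,
    kept_blocks: int | None = 4,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-chemical feature vectors into (X, labels, chemical_ids)."""
    if not tcrc_sets:
        raise EmptyInputError("no TCRC sets to featurize")
    rows = [
        featurize(s, n_concentrations, include_nc, level, kept_blocks).values
        for s in tcrc_sets
    ]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ShapeError(f"inconsistent feature lengths across chemicals: {sorted(lengths)}")
    labels = np.array([s.label if s.label is not None else "" for s in tcrc_sets])
    ids = [s.chemical_id for s in tcrc_sets]
    return np.vstack(rows), labels, ids
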