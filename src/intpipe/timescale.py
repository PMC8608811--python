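"""Intrinsic neural timescale (INT) estimation.

The INT index of a time series is the sum of the leading positive sample
autocorrelation values (scanning from lag 1 until the ACF first goes
negative) multiplied by the repetition time.  Multi-session series are
handled by estimating per session and averaging; the ACF is never computed
across a session boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AcfSequence",
    "IntMap",
    "sample_acf",
    "int_index",
    "int_from_series",
    "int_map",
    "split_sessions",
]


@dataclass(frozen=True)
class AcfSequence:
    """Sample autocorrelation values at lags ``0..K``.

    ``degenerate`` marks a constant (zero-variance) input for which no ACF
    exists; downstream the INT of a degenerate series is defined as 0.
    """

    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def max_lag(self) -> int:
        return self.values.size - 1


@dataclass
class IntMap:
    """3-D grid of INT values in seconds, defined under a brain mask."""

    grid: np.ndarray
    mask: np.ndarray
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.shape != self.mask.shape:
            raise ValueError(
                f"grid shape {self.grid.shape} != mask shape {self.mask.shape}"
            )

    @property
    def values(self) -> np.ndarray:
        """In-mask INT values as a flat vector (C order)."""
        return self.grid[self.mask]


def _acf_matrix(data: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Biased (1/T denominator) sample ACF of each row of ``data``.

    Returns ``(acf, degenerate)`` where ``acf`` has shape
    ``(n_series, max_lag + 1)`` and ``degenerate`` flags zero-variance rows
    (their ACF rows are all zero).  Uses FFT autocorrelation, which is exact
    for this estimator up to floating-point error.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_series, n = data.shape
    if max_lag >= n:
        raise ValueError(f"max_lag={max_lag} must be < series length {n}")
    x = data - data.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, : max_lag + 1]
    denom = acov[:, 0].copy()
    # exactly-constant rows leave only rounding residue after mean removal
    constant = data.max(axis=1) == data.min(axis=1)
    degenerate = constant | (denom <= 0.0)
    denom[degenerate] = 1.0
    acf = acov / denom[:, None]
    acf[degenerate] = 0.0
    acf[~degenerate, 0] = 1.0
    return acf, degenerate


def sample_acf(values: Sequence[float], max_lag: int | None = None) -> AcfSequence:
    """Sample autocorrelation of a single-session series at lags ``0..max_lag``.

    Uses the conventional biased estimator: mean-removed autocovariances with
    a 1/T denominator, normalised by the lag-0 autocovariance, so the result
    is a valid autocorrelation sequence with ACF(0) = 1.

    A constant series yields a degenerate :class:`AcfSequence` rather than an
    exception; ``max_lag`` defaults to ``T // 2``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample_acf expects a 1-D series")
    if x.size < 2:
        raise ValueError(f"series too short ({x.size} frames; need >= 2)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if max_lag is None:
        max_lag = x.size // 2
    acf, degenerate = _acf_matrix(x[None, :], max_lag)
    return AcfSequence(values=acf[0], degenerate=bool(degenerate[0]))


def int_index(
    acf: AcfSequence | Sequence[float],
    tr: float,
    include_lag0: bool = False,
) -> float:
    """INT in seconds from an ACF sequence.

    Scans lags >= 1 until the first strictly negative ACF value and sums the
    values before it (an exactly-zero value is included and scanning
    continues).  The sum is multiplied by ``tr``.  When ``include_lag0`` is
    true the lag-0 value (1 by definition) joins the sum.  If no negative
    value occurs within the sequence, all available lags are summed and a
    truncation warning is logged.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    if isinstance(acf, AcfSequence):
        if acf.degenerate:
            return 0.0
        vals = acf.values
    else:
        vals = np.asarray(acf, dtype=float)
    v = vals[1:]
    neg = np.flatnonzero(v < 0)
    if neg.size:
        total = float(v[: neg[0]].sum())
    else:
        total = float(v.sum())
        logger.warning(
            "ACF never went negative within %d lags; INT sum truncated", v.size
        )
    if include_lag0:
        total += 1.0
    return tr * total


def split_sessions(n_frames: int, sessions: Sequence[int] | None) -> list[slice]:
    """Frame slices for per-session processing.

    ``sessions`` lists per-session frame counts and must sum to ``n_frames``;
    ``None`` means a single session.
    """
    if sessions is None:
        return [slice(0, n_frames)]
    sessions = [int(s) for s in sessions]
    if any(s < 2 for s in sessions):
        raise ValueError(f"every session needs >= 2 frames, got {sessions}")
    if sum(sessions) != n_frames:
        raise ValueError(
            f"session lengths {sessions} sum to {sum(sessions)}, expected {n_frames}"
        )
    bounds = np.concatenate([[0], np.cumsum(sessions)])
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def int_from_series(
    values: Sequence[float],
    tr: float,
    sessions: Sequence[int] | None = None,
    max_lag: int | None = None,
    include_lag0: bool = False,
) -> float:
    """INT of one (possibly multi-session) series, in seconds.

    The index is computed independently per session and averaged; a
    degenerate (constant) session contributes 0.
    """
    x = np.asarray(values, dtype=float)
    per_session = []
    for sl in split_sessions(x.size, sessions):
        seg = x[sl]
        lag = max_lag if max_lag is not None else seg.size // 2
        acf = sample_acf(seg, max_lag=lag)
        per_session.append(int_index(acf, tr, include_lag0=include_lag0))
    return float(np.mean(per_session))


def _int_vector(
    data: np.ndarray,
    tr: float,
    max_lag: int,
    include_lag0: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised single-session INT for rows of ``data`` (n_series, T).

    Returns ``(int_seconds, degenerate)``.  Implements exactly the scalar
    rule: sum ACF lags 1..m-1 where m is the first lag with a strictly
    negative value, times ``tr``.
    """
    acf, degenerate = _acf_matrix(data, max_lag)
    v = acf[:, 1:]
    is_neg = v < 0
    has_neg = is_neg.any(axis=1)
    first_neg = np.where(has_neg, is_neg.argmax(axis=1), v.shape[1])
    csum = np.concatenate([np.zeros((v.shape[0], 1)), np.cumsum(v, axis=1)], axis=1)
    total = np.take_along_axis(csum, first_neg[:, None], axis=1)[:, 0]
    n_trunc = int((~has_neg & ~degenerate).sum())
    if n_trunc:
        logger.warning(
            "%d series had no negative ACF within %d lags; sums truncated",
            n_trunc,
            v.shape[1],
        )
    if include_lag0:
        total = total + 1.0
    total[degenerate] = 0.0
    return tr * total, degenerate


def int_map(
    volume: np.ndarray,
    mask: np.ndarray,
    tr: float,
    sessions: Sequence[int] | None = None,
    max_lag: int | None = None,
    include_lag0: bool = False,
    affine: np.ndarray | None = None,
) -> IntMap:
    """Per-voxel INT map of a 4-D volume under a 3-D brain mask.

    Every in-mask voxel is treated as an independent series (per-session
    estimation, averaged across sessions); out-of-mask voxels are NaN.
    Degenerate (constant) voxels get INT 0 and are counted in the log and in
    ``IntMap.n_degenerate``.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {volume.shape}")
    if volume.shape[:3] != mask.shape:
        raise ValueError(
            f"volume spatial shape {volume.shape[:3]} != mask shape {mask.shape}"
        )
    if not mask.any():
        raise ValueError("mask selects zero voxels")
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")

    data = volume[mask]  # (V, T)
    n_frames = data.shape[1]
    slices = split_sessions(n_frames, sessions)

    per_session = np.zeros((len(slices), data.shape[0]))
    degenerate_any = np.zeros(data.shape[0], dtype=bool)
    for i, sl in enumerate(slices):
        seg = data[:, sl]
        lag = max_lag if max_lag is not None else seg.shape[1] // 2
        vals, degen = _int_vector(seg, tr, lag, include_lag0)
        per_session[i] = vals
        degenerate_any |= degen
    values = per_session.mean(axis=0)

    n_degen = int(degenerate_any.sum())
    if n_degen:
        logger.warning("%d in-mask voxels were degenerate (constant series)", n_degen)

    grid = np.full(mask.shape, np.nan)
    grid[mask] = values
    return IntMap(
        grid=grid,
        mask=mask,
        tr=tr,
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
        n_degenerate=n_degen,
    )
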