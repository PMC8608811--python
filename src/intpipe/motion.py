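"""Framewise displacement and greedy FD group matching.

FD follows the Power convention: sum of absolute backward differences of
the six rigid-body parameters, with rotations converted to arc length on a
50 mm sphere.  Group matching is a two-phase greedy elimination: drop the
highest-FD patients until the Welch p on FD clears alpha, then drop the
lowest-FD controls while doing so still shrinks the absolute group mean
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FdSummary",
    "FdMatchResult",
    "framewise_displacement",
    "fd_match",
    "load_motion_params",
]


@dataclass(frozen=True)
class FdSummary:
    subject_id: str
    mean_fd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_fd) or self.mean_fd < 0:
            raise ValueError(
                f"mean FD must be finite and nonnegative, got {self.mean_fd} "
                f"for {self.subject_id!r}"
            )


@dataclass
class FdMatchResult:
    """Outcome of the two-phase FD elimination."""

    kept_hc: list[FdSummary]
    kept_sz: list[FdSummary]
    removed_hc: list[FdSummary] = field(default_factory=list)
    removed_sz: list[FdSummary] = field(default_factory=list)
    final_p: float = float("nan")
    mean_fd_hc: float = float("nan")
    mean_fd_sz: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "kept_hc": [s.subject_id for s in self.kept_hc],
            "kept_sz": [s.subject_id for s in self.kept_sz],
            "removed_hc": [s.subject_id for s in self.removed_hc],
            "removed_sz": [s.subject_id for s in self.removed_sz],
            "final_p": self.final_p,
            "mean_fd_hc": self.mean_fd_hc,
            "mean_fd_sz": self.mean_fd_sz,
        }


def framewise_displacement(trace: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Per-frame FD (mm) from a (T, 6) motion-parameter array.

    Columns are translations x/y/z in millimetres then rotations in radians.
    ``FD_t = sum |Δ translation| + radius * sum |Δ rotation|`` for t >= 2;
    the first frame has FD 0.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"expected a (T, 6) parameter array, got {trace.shape}")
    if trace.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    bad = ~np.isfinite(trace)
    if bad.any():
        frame = int(np.argwhere(bad)[0, 0])
        raise ValueError(f"non-finite motion parameter at frame {frame}")
    delta = np.abs(np.diff(trace, axis=0))
    fd = np.zeros(trace.shape[0])
    fd[1:] = delta[:, :3].sum(axis=1) + radius * delta[:, 3:].sum(axis=1)
    return fd


def load_motion_params(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited 6-column motion parameter file."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, found {arr.shape[1]}")
    return arr


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _fds(group: Sequence[FdSummary]) -> np.ndarray:
    return np.array([s.mean_fd for s in group])


def fd_match(
    hc: Sequence[FdSummary],
    sz: Sequence[FdSummary],
    alpha: float = 0.05,
    min_group: int = 10,
) -> FdMatchResult:
    """Two-phase greedy FD outlier elimination.

    Phase 1: while the Welch p on mean FD is below ``alpha``, remove the
    patient with the largest FD.  Phase 2: remove the control with the
    smallest FD as long as doing so strictly decreases the absolute group
    mean FD difference.  Ties on FD are broken by subject_id so the result
    is deterministic.  Raises if phase 1 cannot reach ``alpha`` without
    shrinking the patient group below ``min_group``.
    """
    if len(hc) < min_group or len(sz) < min_group:
        raise ValueError(
            f"both groups need >= {min_group} subjects (HC={len(hc)}, SZ={len(sz)})"
        )
    # ascending by (FD, id): phase 1 pops from the tail, phase 2 from the head
    hc_sorted = sorted(hc, key=lambda s: (s.mean_fd, s.subject_id))
    sz_sorted = sorted(sz, key=lambda s: (s.mean_fd, s.subject_id))
    removed_hc: list[FdSummary] = []
    removed_sz: list[FdSummary] = []

    p = _welch_p(_fds(hc_sorted), _fds(sz_sorted))
    while p < alpha:
        if len(sz_sorted) <= min_group:
            raise ValueError(
                f"FD matching failed: patient group at min size {min_group} "
                f"with Welch p={p:.3g} < alpha={alpha}"
            )
        removed_sz.append(sz_sorted.pop())
        p = _welch_p(_fds(hc_sorted), _fds(sz_sorted))

    diff = abs(_fds(hc_sorted).mean() - _fds(sz_sorted).mean())
    while len(hc_sorted) > min_group:
        candidate = hc_sorted[1:]
        new_diff = abs(_fds(candidate).mean() - _fds(sz_sorted).mean())
        if new_diff < diff:
            removed_hc.append(hc_sorted.pop(0))
            diff = new_diff
        else:
            break

    return FdMatchResult(
        kept_hc=hc_sorted,
        kept_sz=sz_sorted,
        removed_hc=removed_hc,
        removed_sz=removed_sz,
        final_p=_welch_p(_fds(hc_sorted), _fds(sz_sorted)),
        mean_fd_hc=float(_fds(hc_sorted).mean()),
        mean_fd_sz=float(_fds(sz_sorted).mean()),
    )
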