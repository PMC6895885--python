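"""Sliding-window dynamic functional connectivity estimation.

A rectangular window of ``window_seconds`` (default 40 s, converted to TRs
by rounding) slides along the ROI time courses in steps of ``step_trs``
(default 5). Within each window the Pearson correlation between every ROI
pair is computed, the upper triangle of the R x R correlation matrix is
vectorized in the canonical pair order and Fisher-z transformed
(variance-stabilizing atanh). Stacking the window columns gives the dFC
matrix S with one row per connection — the point cloud every later stage
(dimension estimation, embedding, clustering, coreness) operates on.

Incomplete trailing windows are dropped: correlations on truncated windows
have a different sampling variance. Correlations are clipped at 1 - 1e-7
in magnitude before atanh, which is undefined at |r| = 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import NumericError, PairIndex, ValidationError

R_CLIP_EPS = 1e-7

__all__ = ["WindowPlan", "DfcMatrix", "make_window_plan", "sliding_window_dfc",
           "fisher_z", "inverse_fisher_z"]


@dataclasses.dataclass(frozen=True)
class WindowPlan:
    """Sliding-window layout: L-TR windows every ``step_trs`` TRs."""

    window_seconds: float
    step_trs: int
    tr_seconds: float
    T: int

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValidationError(f"TR must be positive, got {self.tr_seconds}")
        if self.step_trs < 1:
            raise ValidationError(f"step must be >= 1 TR, got {self.step_trs}")
        if self.L < 4:
            raise ValidationError(
                f"window of {self.window_seconds} s at TR={self.tr_seconds} s is "
                f"{self.L} TRs; need >= 4 for a stable correlation"
            )
        if self.T < self.L:
            raise ValidationError(
                f"series of T={self.T} TRs shorter than one {self.L}-TR window"
            )

    @property
    def L(self) -> int:
        """Window length in TRs: round(window_seconds / TR)."""
        return int(round(self.window_seconds / self.tr_seconds))

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.D) * self.step_trs

    @property
    def D(self) -> int:
        """Number of complete windows: floor((T - L) / step) + 1."""
        return (self.T - self.L) // self.step_trs + 1


@dataclasses.dataclass
class DfcMatrix:
    """The n x D dFC matrix: Fisher-z correlation trajectories per pair."""

    S: np.ndarray
    pair_index: PairIndex
    plan: WindowPlan

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (self.pair_index.n, self.plan.D):
            raise ValidationError(
                f"S shape {self.S.shape} != (n_pairs={self.pair_index.n}, D={self.plan.D})"
            )
        if not np.all(np.isfinite(self.S)):
            raise ValidationError("dFC matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def D(self) -> int:
        return self.S.shape[1]


def make_window_plan(T: int, tr_seconds: float, window_seconds: float = 40.0,
                     step_trs: int = 5) -> WindowPlan:
    """Build the sliding-window layout for a T-TR series."""
    return WindowPlan(window_seconds=window_seconds, step_trs=step_trs,
                      tr_seconds=tr_seconds, T=T)


def fisher_z(r):
    """Fisher z = atanh(r), with |r| clipped at 1 - 1e-7 so the output is finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValidationError("correlation outside [-1, 1]")
    return np.arctanh(np.clip(r, -(1 - R_CLIP_EPS), 1 - R_CLIP_EPS))


def inverse_fisher_z(z):
    """Inverse transform: r = tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def sliding_window_dfc(ts, plan: WindowPlan | None = None, *,
                       impute_zero_variance: bool = False) -> DfcMatrix:
    """Estimate the dFC matrix S from ROI time courses.

    Column w of S is the Fisher-z upper triangle of the Pearson correlation
    matrix of window w, in canonical pair order. A zero-variance ROI within
    a window raises :class:`NumericError` naming the ROI and window unless
    ``impute_zero_variance`` sets its correlations to z = 0.
    """
    if plan is None:
        plan = make_window_plan(ts.T, ts.tr_seconds)
    if plan.T != ts.T or plan.tr_seconds != ts.tr_seconds:
        raise ValidationError("window plan does not match the time series")
    pidx = PairIndex(ts.R)
    iu = np.triu_indices(ts.R, k=1)
    S = np.empty((pidx.n, plan.D))
    for w, start in enumerate(plan.starts):
        seg = ts.data[start:start + plan.L]
        sd = seg.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size and not impute_zero_variance:
            raise NumericError(
                f"ROI {ts.roi_ids[dead[0]]!r} has zero variance in window {w} "
                f"(TRs {start}..{start + plan.L - 1}); enable zero-variance "
                f"imputation to map its correlations to z=0"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(seg, rowvar=False)
        if dead.size:
            C[dead, :] = 0.0
            C[:, dead] = 0.0
        S[:, w] = fisher_z(C[iu])
    return DfcMatrix(S=S, pair_index=pidx, plan=plan)
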