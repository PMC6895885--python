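"""Similarity and group statistics on core-quality maps.

* :func:`eta2` — spatial similarity of two matrices, contrasting
  within-position variance against total variance:
  eta2 = 1 - sum[(a_i - m_i)^2 + (b_i - m_i)^2] / sum[(a_i - M)^2 + (b_i - M)^2],
  m_i the position-wise mean and M the grand mean of both inputs. It is 1
  only for identical inputs and is invariant to a common additive shift.
* :func:`paired_ttest_fwer` — per-connection paired t-tests with
  family-wise error control (Holm step-down by default, Bonferroni
  optionally).
* :func:`permutation_test` — label-permutation test of class mean
  differences with the add-one (conservative, never-zero) p estimator.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError

__all__ = ["StatMap", "PermutationResult", "eta2", "paired_ttest_fwer",
           "permutation_test"]


@dataclasses.dataclass
class StatMap:
    """Per-feature test results with FWER-controlled decisions."""

    t: np.ndarray
    p: np.ndarray
    reject: np.ndarray          # boolean at FWER level alpha
    mean_diff: np.ndarray       # cond1 - cond2
    alpha: float
    method: str                 # holm | bonferroni
    n_subjects: int
    paired: bool = True


@dataclasses.dataclass
class PermutationResult:
    """Empirical permutation-test results."""

    observed: np.ndarray        # class mean difference per feature
    p: np.ndarray               # add-one two-sided empirical p
    B: int
    seed: int


def eta2(Ca: np.ndarray, Cb: np.ndarray) -> float:
    """Similarity of two equally shaped maps; 1 iff identical.

    Symmetric square matrices are compared on their vectorized upper
    triangles (mirrored cells would otherwise be double-counted); anything
    else is compared elementwise on the flattened finite entries.
    """
    Ca = np.asarray(Ca, dtype=float)
    Cb = np.asarray(Cb, dtype=float)
    if Ca.shape != Cb.shape:
        raise ValidationError(f"shape mismatch: {Ca.shape} vs {Cb.shape}")
    if Ca.ndim == 2 and Ca.shape[0] == Ca.shape[1]:
        sym_a = np.allclose(Ca, Ca.T, equal_nan=True)
        sym_b = np.allclose(Cb, Cb.T, equal_nan=True)
        if sym_a and sym_b:
            iu = np.triu_indices(Ca.shape[0], k=1)
            Ca, Cb = Ca[iu], Cb[iu]
    a, b = Ca.ravel(), Cb.ravel()
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValidationError("need at least 2 comparable positions")
    m = (a + b) / 2.0
    grand = m.mean()
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    den = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if den == 0:
        raise ValidationError("eta2 undefined: both maps constant and equal")
    return float(1.0 - num / den)


def paired_ttest_fwer(X_cond1: np.ndarray, X_cond2: np.ndarray,
                      alpha: float = 0.05, method: str = "holm") -> StatMap:
    """Per-feature paired t-test with family-wise error control.

    Rows are subjects (same subjects, same order, in both conditions),
    columns are features (connections). Features whose paired differences
    have zero variance get t = 0, p = 1 with a warning.
    """
    X1 = np.atleast_2d(np.asarray(X_cond1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X_cond2, dtype=float))
    if X1.shape != X2.shape:
        raise ValidationError(f"condition shapes differ: {X1.shape} vs {X2.shape}")
    n = X1.shape[0]
    if n < 3:
        raise ValidationError(f"need >= 3 subjects for a paired t-test, got {n}")
    if method not in ("holm", "bonferroni"):
        raise ValidationError(f"unknown FWER method {method!r}")
    diff = X1 - X2
    degenerate = diff.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = scipy.stats.ttest_rel(X1, X2, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} features have zero-variance paired "
            "differences; setting t=0, p=1",
            RuntimeWarning, stacklevel=2,
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    reject, _, _, _ = multipletests(p, alpha=alpha, method=method)[:4]
    return StatMap(t=t, p=p, reject=reject, mean_diff=diff.mean(axis=0),
                   alpha=alpha, method=method, n_subjects=n, paired=True)


def permutation_test(X: np.ndarray, labels: np.ndarray, B: int = 1000,
                     seed: int = 0, paired: bool = False) -> PermutationResult:
    """Label-permutation test of the per-feature class mean difference.

    Two-sided empirical p with the add-one estimator
    p = (1 + #{|T_perm| >= |T_obs|}) / (B + 1), so p in [1/(B+1), 1].
    For ``paired=True`` rows are subject pairs of differences and the
    permutation is a within-subject sign flip (condition-label exchange).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if B < 100:
        warnings.warn(f"B={B} permutations is low; p-value resolution is 1/{B + 1}",
                      RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    if paired:
        obs = X.mean(axis=0)
        count = np.zeros(X.shape[1])
        for _ in range(B):
            signs = rng.choice([-1.0, 1.0], size=X.shape[0])
            count += np.abs((signs[:, None] * X).mean(axis=0)) >= np.abs(obs) - 1e-12
    else:
        classes = np.unique(labels)
        if classes.size != 2:
            raise ValidationError(f"need exactly 2 classes, got {classes.size}")
        mask = labels == classes[0]
        if mask.all() or not mask.any():
            raise ValidationError("one class is empty")
        obs = X[mask].mean(axis=0) - X[~mask].mean(axis=0)
        count = np.zeros(X.shape[1])
        perm_mask = mask.copy()
        for _ in range(B):
            rng.shuffle(perm_mask)
            stat = X[perm_mask].mean(axis=0) - X[~perm_mask].mean(axis=0)
            count += np.abs(stat) >= np.abs(obs) - 1e-12
    p = (1.0 + count) / (B + 1.0)
    return PermutationResult(observed=obs, p=p, B=B, seed=seed)
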