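"""Synthetic fixtures with planted ground truth.

Four generators cover every stage of the pipeline:

* :func:`gen_dfc_direct` — a connections x windows dFC matrix whose rows
  group into M prototype correlation time courses plus Gaussian noise, for
  testing embedding + CCP clustering recovery.
* :func:`gen_roi_timeseries_tv` — ROI-level series drawn from a
  time-varying block covariance with sinusoidally modulated between-block
  coupling, for testing sliding-window dFC estimation.
* :func:`gen_core_periphery_graph` — a stochastic block model with a
  planted core (dense core-core, intermediate core-periphery, sparse
  periphery-periphery), for testing coreness detection.
* :func:`gen_two_class_coreness` — a two-class feature table with a
  designated discriminative subset, for testing the classification protocol.

All generators are pure functions of their parameters and a seed. One
global seed expands into per-generator substreams (named spawn keys), so
adding a generator call never shifts another generator's draws. Planted
structure is returned alongside the data so downstream recovery can be
scored.

None of this emulates hemodynamics, scanner noise or motion; see the
methods note for what passing these fixtures does and does not show.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np

from .core_io import RoiTimeSeries, ValidationError

__all__ = [
    "SyntheticSpec",
    "gen_dfc_direct",
    "gen_roi_timeseries_tv",
    "gen_core_periphery_graph",
    "gen_two_class_coreness",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the global seed: stable under added generators."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclasses.dataclass
class SyntheticSpec:
    """Planted ground truth describing one synthetic dataset."""

    seed: int
    M: int = 6                      # planted module (prototype) count
    n: int = 435                    # connections (dFC mode) or nodes (graph mode)
    D: int = 120                    # windows (dFC mode) / timepoints (ROI mode)
    snr: float = 3.0                # prototype amplitude / noise sd
    prototype: str = "sinusoid"     # or "randomwalk"
    core_fraction: float = 0.2
    p_cc: float = 0.9
    p_cp: float = 0.5
    p_pp: float = 0.05


# ---------------------------------------------------------------------------
# dFC matrix with planted modules
# ---------------------------------------------------------------------------

def _prototypes(M: int, D: int, kind: str, rng: np.random.Generator,
                amplitude: float) -> np.ndarray:
    """M near-orthogonal prototype time courses of length D, given amplitude (rms)."""
    if kind == "sinusoid":
        t = np.arange(D)
        G = np.empty((M, D))
        for m in range(M):
            # distinct integer frequencies -> near-orthogonal over the window span
            freq = m + 1
            phase = rng.uniform(0, 2 * np.pi)
            G[m] = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t / D + phase)
    elif kind == "randomwalk":
        steps = rng.standard_normal((M, D))
        G = np.cumsum(steps, axis=1)
        # smooth and orthogonalize so modules are distinguishable
        kernel = np.ones(5) / 5.0
        G = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, G)
        G -= G.mean(axis=1, keepdims=True)
        Q, _ = np.linalg.qr(G.T)
        G = Q[:, :M].T * np.sqrt(D)
    else:
        raise ValidationError(f"unknown prototype kind {kind!r}")
    # unit rms rows scaled to the requested amplitude
    G /= np.sqrt(np.mean(G**2, axis=1, keepdims=True))
    return amplitude * G


def gen_dfc_direct(spec: SyntheticSpec, amplitude: float = 0.8,
                   amplitude_spread: float = 0.5,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Connections x windows dFC matrix with M planted row modules.

    Row i is ``a_i * g_{m(i)} + eps`` with ``eps ~ N(0, (amplitude/snr)^2)``
    and the per-connection coupling strength ``a_i`` uniform in
    ``amplitude * [1 - spread/2, 1 + spread/2]`` — connections sharing a
    prototype differ in how strongly they express it, so a module traces a
    ray rather than collapsing onto a single point. The sum is squashed
    through tanh into a valid correlation trajectory and Fisher-z
    transformed, so rows live on the scale the estimation stage produces.

    Returns ``(S, membership, prototypes)`` where ``S`` is (n, D),
    ``membership`` maps each row to its module and ``prototypes`` is (M, D)
    in pre-squash units.
    """
    if spec.snr <= 0:
        raise ValidationError(f"snr must be positive, got {spec.snr}")
    if spec.M < 2:
        raise ValidationError(f"need M >= 2 modules, got {spec.M}")
    rng = _rng(spec.seed, "dfc_direct")
    G = _prototypes(spec.M, spec.D, spec.prototype, rng, amplitude)
    # near-equal module sizes covering all n connections
    membership = np.arange(spec.n) % spec.M
    rng.shuffle(membership)
    noise_sd = amplitude / spec.snr
    strengths = rng.uniform(1 - amplitude_spread / 2, 1 + amplitude_spread / 2,
                            spec.n)
    raw = strengths[:, None] * G[membership] \
        + noise_sd * rng.standard_normal((spec.n, spec.D))
    r = np.tanh(raw)                       # valid correlations in (-1, 1)
    S = np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7))  # Fisher z
    return S, membership, G


# ---------------------------------------------------------------------------
# ROI time series with time-varying block covariance
# ---------------------------------------------------------------------------

def _nearest_pd(C: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PD matrix (eigenvalue clip)."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() > eps:
        return C
    w = np.clip(w, eps, None)
    C2 = (V * w) @ V.T
    # restore unit diagonal (correlation matrix)
    d = np.sqrt(np.diag(C2))
    return C2 / np.outer(d, d)


def gen_roi_timeseries_tv(
    R: int,
    T: int,
    tr_seconds: float,
    seed: int,
    n_blocks: int = 2,
    within_rho: float = 0.6,
    modulated_pairs: list[tuple[int, int]] | None = None,
    rho_max: float = 0.8,
    period_seconds: float | None = None,
) -> tuple[RoiTimeSeries, np.ndarray, np.ndarray]:
    """ROI series from a slowly modulated block-correlation model.

    ROIs are split into ``n_blocks`` equal blocks with fixed within-block
    correlation ``within_rho``. For each block pair listed in
    ``modulated_pairs`` the between-block correlation follows
    ``rho(t) = rho_max * (1 + sin(2*pi*t/P)) / 2`` (range [0, rho_max]);
    unlisted pairs stay at 0. Each timepoint is drawn independently from
    ``N(0, Sigma_t)``, with ``Sigma_t`` projected to the nearest positive
    definite correlation matrix when the assembled blocks are not PD.

    Returns ``(ts, block_of_roi, rho_schedule)`` where ``rho_schedule`` is
    (T, n_modulated) with the true between-block correlation at each
    timepoint.
    """
    if not (0 <= within_rho < 1) or not (0 <= rho_max < 1):
        raise ValidationError("correlations must lie in [0, 1)")
    if modulated_pairs is None:
        modulated_pairs = [(0, 1)] if n_blocks >= 2 else []
    if period_seconds is None:
        period_seconds = T * tr_seconds / 3.0
    rng = _rng(seed, "roi_timeseries_tv")
    block_of = np.arange(R) % n_blocks
    t_sec = np.arange(T) * tr_seconds
    schedule = np.empty((T, len(modulated_pairs)))
    X = np.empty((T, R))
    base = np.eye(R)
    for a in range(n_blocks):
        for b in range(n_blocks):
            mask = np.outer(block_of == a, block_of == b)
            if a == b:
                base[mask] = within_rho
    np.fill_diagonal(base, 1.0)
    for t in range(T):
        Sigma = base.copy()
        for q, (a, b) in enumerate(modulated_pairs):
            rho_t = rho_max * (1 + np.sin(2 * np.pi * t_sec[t] / period_seconds)) / 2.0
            schedule[t, q] = rho_t
            mask = np.outer(block_of == a, block_of == b)
            Sigma[mask | mask.T] = rho_t
        Sigma = _nearest_pd(Sigma)
        L = np.linalg.cholesky(Sigma)
        X[t] = L @ rng.standard_normal(R)
    ts = RoiTimeSeries(data=X, tr_seconds=tr_seconds,
                       roi_ids=[f"roi{r + 1}" for r in range(R)])
    return ts, block_of, schedule


# ---------------------------------------------------------------------------
# Planted core-periphery graph
# ---------------------------------------------------------------------------

def gen_core_periphery_graph(
    n_nodes: int,
    core_fraction: float,
    p_cc: float,
    p_cp: float,
    p_pp: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic block graph with a planted core.

    Edges are sampled independently: probability ``p_cc`` within the core
    block (first ``round(core_fraction * n)`` nodes), ``p_cp`` between core
    and periphery, ``p_pp`` within the periphery. Returns a symmetric 0/1
    adjacency with zero diagonal and the boolean core-membership vector.
    """
    for name, p in (("p_cc", p_cc), ("p_cp", p_cp), ("p_pp", p_pp)):
        if not (0 <= p <= 1):
            raise ValidationError(f"{name}={p} outside [0, 1]")
    if not (0 < core_fraction < 1):
        raise ValidationError(f"core_fraction={core_fraction} outside (0, 1)")
    rng = _rng(seed, "core_periphery_graph")
    n_core = int(round(core_fraction * n_nodes))
    is_core = np.zeros(n_nodes, dtype=bool)
    is_core[:n_core] = True
    P = np.where(np.outer(is_core, is_core), p_cc,
                 np.where(np.outer(~is_core, ~is_core), p_pp, p_cp))
    U = rng.random((n_nodes, n_nodes))
    U = np.triu(U, k=1)
    A = (U < P) & (np.triu(np.ones((n_nodes, n_nodes), dtype=bool), k=1))
    A = (A | A.T).astype(np.int8)
    return A, is_core


# ---------------------------------------------------------------------------
# Two-class coreness-like feature table
# ---------------------------------------------------------------------------

def gen_two_class_coreness(
    n_features: int,
    n_per_class: int,
    effect_size: float,
    seed: int,
    n_discriminative: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class Gaussian features with a designated discriminative subset.

    The first ``n_discriminative`` features differ between classes by
    ``effect_size`` standard deviations; all others are pure noise. Returns
    ``(X, y, discriminative_mask)`` with y in {0, 1}.
    """
    if effect_size < 0:
        raise ValidationError(f"effect_size must be >= 0, got {effect_size}")
    if n_per_class < 2:
        raise ValidationError(f"need n_per_class >= 2, got {n_per_class}")
    if n_discriminative > n_features:
        raise ValidationError("more discriminative features than features")
    rng = _rng(seed, "two_class_coreness")
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    y = np.repeat([0, 1], n_per_class)
    mask = np.zeros(n_features, dtype=bool)
    mask[:n_discriminative] = True
    X[np.ix_(y == 1, mask)] += effect_size
    return X, y, mask
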