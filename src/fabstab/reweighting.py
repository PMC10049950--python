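"""MBAR reweighting of umbrella-sampling windows into PMF profiles.

The estimator combines the biased samples of all windows into a single set
of unbiased per-frame weights by solving the multistate Bennett acceptance
ratio (MBAR) self-consistent equations

    f_i = -ln sum_n exp(-u_in) / sum_k N_k exp(f_k - u_kn)

for the per-window dimensionless free energies ``f`` (gauge f_0 = 0), with
``u_kn`` the reduced harmonic bias energy of pooled sample ``n`` evaluated
in window ``k``.  The solver runs log-sum-exp-stabilized self-consistent
iterations far from the solution and Newton steps on the equivalent convex
maximum-likelihood objective near it.

Unbiased weights feed the PMF (``F_b = -kT ln sum_{n in b} w_n``), a
window-level block-bootstrap uncertainty, the trajectory-splitting
convergence diagnostic, and the reweighted occurrence of interface contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import KB, T_DEFAULT, kt

__all__ = [
    "UmbrellaWindow", "MBARResult", "PMFProfile",
    "make_window_ladder", "reduced_bias_matrix", "solve_mbar",
    "pmf_from_weights", "pmf_uncertainty", "convergence_split",
    "reweighted_occurrence", "solve_windows", "estimate_pmf",
]


@dataclass
class UmbrellaWindow:
    """One biased sampling window (post-discard CV samples)."""

    index: int
    center: float        # nm
    spring: float        # kJ mol^-1 nm^-2
    temperature: float   # K
    samples: np.ndarray  # nm
    n_discarded: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.spring <= 0:
            raise ValueError("spring must be positive")
        if self.samples.size < 1:
            raise ValueError("window needs at least one post-discard sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class MBARResult:
    """Solved MBAR state: window free energies and pooled-frame weights."""

    f: np.ndarray          # (K,), dimensionless, f[0] = 0
    weights: np.ndarray    # (N,), unbiased, sums to 1
    iterations: int
    residual: float        # max |delta f| of a final self-consistent update
    converged: bool
    temperature: float = T_DEFAULT


@dataclass
class PMFProfile:
    """Binned potential of mean force, minimum of occupied bins at 0."""

    edges: np.ndarray          # (B+1,), nm, strictly increasing
    free_energy: np.ndarray    # (B,), kJ/mol; NaN on empty bins
    uncertainty: np.ndarray | None  # (B,), kJ/mol
    occupied: np.ndarray       # (B,), bool
    temperature: float = T_DEFAULT

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        sig = self.uncertainty if self.uncertainty is not None \
            else np.full(len(self.free_energy), np.nan)
        return pd.DataFrame({
            "bin_lo_nm": self.edges[:-1], "bin_hi_nm": self.edges[1:],
            "F_kJmol": self.free_energy, "sigma_kJmol": sig,
            "occupied": self.occupied,
        })


# --------------------------------------------------------------------------- #
# Window ladder
# --------------------------------------------------------------------------- #

def _segment(lo, hi, step):
    n = int(round((hi - lo) / step))
    centers = lo + step * np.arange(n + 1)
    if centers[-1] > hi + 1e-9 or abs(centers[-1] - hi) > 1e-9:
        warnings.warn(f"segment [{lo}, {hi}] not commensurate with step {step}; "
                      "clamping last center to the segment end")
        centers = centers[centers <= hi + 1e-9]
        if abs(centers[-1] - hi) > 1e-9:
            centers = np.append(centers, hi)
    return centers


def make_window_ladder(lo: float = 1.7, mid_lo: float = 2.0, mid_hi: float = 2.5,
                       hi: float = 4.0, coarse_step: float = 0.1,
                       fine_step: float = 0.05) -> np.ndarray:
    """Asymmetric umbrella-window centers: coarse / fine / coarse segments.

    The defaults enumerate a coarse 0.1 nm spacing on [lo, mid_lo] and
    [mid_hi, hi] and a fine 0.05 nm spacing on [mid_lo, mid_hi] (denser where
    the domains dissociate), deduplicated at the segment joins — 29 centers
    from 1.7 to 4.0 nm.
    """
    if not (lo < mid_lo < mid_hi < hi):
        raise ValueError("require lo < mid_lo < mid_hi < hi")
    if coarse_step <= 0 or fine_step <= 0:
        raise ValueError("steps must be positive")
    segs = [_segment(lo, mid_lo, coarse_step),
            _segment(mid_lo, mid_hi, fine_step),
            _segment(mid_hi, hi, coarse_step)]
    centers = segs[0]
    for s in segs[1:]:
        centers = np.concatenate([centers, s[1:]])  # drop duplicate join point
    return np.round(centers, 10)


# --------------------------------------------------------------------------- #
# MBAR
# --------------------------------------------------------------------------- #

def reduced_bias_matrix(windows: list[UmbrellaWindow]):
    """Assemble the reduced bias-energy matrix over the pooled samples.

    Returns ``(u, x_pooled, N_k)`` with
    ``u[k, n] = spring_k (x_n - center_k)^2 / (2 kB T)``.  All windows must
    share one temperature, otherwise the reduced-energy convention would
    differ between rows.
    """
    temps = np.array([w.temperature for w in windows])
    if not np.allclose(temps, temps[0], rtol=1e-9):
        raise ValueError("windows have mixed temperatures")
    x = np.concatenate([w.samples for w in windows])
    centers = np.array([w.center for w in windows])
    springs = np.array([w.spring for w in windows])
    kbt = KB * temps[0]
    u = 0.5 * springs[:, None] * (x[None, :] - centers[:, None]) ** 2 / kbt
    n_k = np.array([w.n_samples for w in windows])
    return u, x, n_k


def _lse(a, axis):
    """Stable log-sum-exp along one axis (lean numpy version)."""
    m = np.max(a, axis=axis, keepdims=True)
    return np.squeeze(m, axis) + np.log(np.exp(a - m).sum(axis=axis))


def _mbar_log_denominator(u, f, log_nk):
    """log c_n = logsumexp_k(log N_k + f_k - u_kn) for every pooled sample."""
    return _lse(log_nk[:, None] + f[:, None] - u, axis=0)


def _sc_update(u, f, log_nk):
    log_c = _mbar_log_denominator(u, f, log_nk)
    f_new = -_lse(-u - log_c[None, :], axis=1)
    return f_new - f_new[0], log_c


def solve_mbar(u: np.ndarray, N_k: np.ndarray, tol: float = 1e-8,
               max_iter: int = 10_000, f_init: np.ndarray | None = None,
               temperature: float = T_DEFAULT) -> MBARResult:
    """Solve the MBAR equations for window free energies and weights.

    Damped Newton steps on the convex maximum-likelihood objective
    ``kappa(f) = sum_n ln sum_k N_k exp(f_k - u_kn) - sum_k N_k f_k``
    (whose stationary point is the MBAR fixed point), falling back to the
    log-sum-exp-stabilized self-consistent update whenever a Newton step
    does not decrease the objective.  Convergence is declared when the
    self-consistent update moves ``f`` by less than ``tol`` (max norm).
    On ``max_iter`` exhaustion the best estimate is returned with
    ``converged=False``.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("reduced energies must be finite")
    K, N = u.shape
    N_k = np.asarray(N_k, dtype=float)
    if int(N_k.sum()) != N:
        raise ValueError("sum of N_k must equal the pooled sample count")
    log_nk = np.log(N_k)
    f = np.zeros(K) if f_init is None else np.asarray(f_init, float) - f_init[0]

    def objective(fv):
        return float(_mbar_log_denominator(u, fv, log_nk).sum() - N_k @ fv)

    iterations = 0
    residual = np.inf
    kappa = objective(f)
    while iterations < max_iter:
        f_sc, log_c = _sc_update(u, f, log_nk)
        residual = float(np.max(np.abs(f_sc - f)))
        iterations += 1
        if residual < tol:
            break
        f_next = None
        if K > 1:
            w_kn = np.exp(log_nk[:, None] + f[:, None] - u - log_c[None, :])
            g = w_kn.sum(axis=1) - N_k
            h = -w_kn @ w_kn.T
            np.fill_diagonal(h, w_kn.sum(axis=1) - np.einsum("kn,kn->k", w_kn, w_kn))
            try:
                step = np.zeros(K)
                step[1:] = np.linalg.solve(h[1:, 1:], -g[1:])
                scale = 1.0
                for _ in range(12):
                    f_try = f + scale * step
                    f_try -= f_try[0]
                    k_try = objective(f_try)
                    if k_try < kappa:
                        f_next, kappa = f_try, k_try
                        break
                    scale *= 0.5
            except np.linalg.LinAlgError:
                pass
        if f_next is None:
            f_next = f_sc
            kappa = objective(f_next)
        f = f_next

    log_c = _mbar_log_denominator(u, f, log_nk)
    log_w = -log_c - _lse(-log_c, axis=0)
    return MBARResult(f=f, weights=np.exp(log_w), iterations=iterations,
                      residual=residual, converged=residual < tol,
                      temperature=temperature)


def solve_windows(windows: list[UmbrellaWindow], tol: float = 1e-8,
                  max_iter: int = 10_000, f_init=None) -> tuple:
    """Convenience: reduced energies + MBAR solve for a window list."""
    u, x, n_k = reduced_bias_matrix(windows)
    result = solve_mbar(u, n_k, tol=tol, max_iter=max_iter, f_init=f_init,
                        temperature=windows[0].temperature)
    return result, x


# --------------------------------------------------------------------------- #
# PMF
# --------------------------------------------------------------------------- #

def pmf_from_weights(cv_samples: np.ndarray, weights, edges,
                     temperature: float = T_DEFAULT) -> PMFProfile:
    """Bin unbiased weights along the CV into a free-energy profile.

    ``F_b = -kB T ln(sum_{n in b} w_n)``, shifted so the minimum occupied bin
    is 0; empty bins are masked (NaN), never interpolated.
    """
    x = np.asarray(cv_samples, dtype=float)
    w = weights.weights if isinstance(weights, MBARResult) else np.asarray(weights, float)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    mass, _ = np.histogram(x, bins=edges, weights=w)
    occupied = mass > 0
    if not occupied.any():
        raise ValueError("all PMF bins are empty")
    kbt = kt(temperature)
    F = np.full(len(mass), np.nan)
    F[occupied] = -kbt * np.log(mass[occupied])
    F -= np.nanmin(F[occupied])
    return PMFProfile(edges=edges, free_energy=F, uncertainty=None,
                      occupied=occupied, temperature=temperature)


def estimate_pmf(windows: list[UmbrellaWindow], edges=None,
                 bin_width: float = 0.05, tol: float = 1e-8) -> PMFProfile:
    """Full ladder -> MBAR -> PMF convenience path."""
    if edges is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        edges = np.arange(lo, hi + bin_width, bin_width)
    result, x = solve_windows(windows, tol=tol)
    return pmf_from_weights(x, result, edges, temperature=windows[0].temperature)


def pmf_uncertainty(windows: list[UmbrellaWindow], edges, n_boot: int = 50,
                    seed: int = 0, n_blocks: int = 10, tol: float = 1e-7
                    ) -> np.ndarray:
    """Per-bin PMF standard deviation by window-level block bootstrap.

    Each replicate resamples contiguous sample blocks with replacement inside
    every window (blocks respect residual time correlation), re-solves MBAR
    (warm-started) and re-bins.  Deterministic given the seed.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")
    rng = np.random.default_rng(seed)
    base, _ = solve_windows(windows, tol=tol)
    edges = np.asarray(edges, dtype=float)
    profiles = np.empty((n_boot, len(edges) - 1))
    for b in range(n_boot):
        rewin = []
        for w in windows:
            blocks = np.array_split(w.samples, min(n_blocks, w.n_samples))
            pick = rng.integers(0, len(blocks), len(blocks))
            samples = np.concatenate([blocks[i] for i in pick])
            rewin.append(UmbrellaWindow(index=w.index, center=w.center,
                                        spring=w.spring, temperature=w.temperature,
                                        samples=samples, n_discarded=w.n_discarded))
        res, x = solve_windows(rewin, tol=tol, f_init=base.f)
        prof = pmf_from_weights(x, res, edges, temperature=windows[0].temperature)
        profiles[b] = prof.free_energy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(profiles, axis=0, ddof=1)


def convergence_split(windows: list[UmbrellaWindow], edges=None,
                      bin_width: float = 0.05):
    """Trajectory-splitting convergence diagnostic.

    Re-runs the MBAR -> PMF pipeline on the first and second half of every
    window and reports ``(pmf_first, pmf_second, max |delta F|)`` over bins
    occupied in both halves.
    """
    for w in windows:
        if w.n_samples < 2:
            raise ValueError(f"window {w.index} has fewer than 2 samples")
    halves = ([], [])
    for w in windows:
        h = w.n_samples // 2
        for i, sl in enumerate((slice(None, h), slice(h, None))):
            halves[i].append(UmbrellaWindow(
                index=w.index, center=w.center, spring=w.spring,
                temperature=w.temperature, samples=w.samples[sl],
                n_discarded=w.n_discarded))
    if edges is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        edges = np.arange(lo, hi + bin_width, bin_width)
    p1 = estimate_pmf(halves[0], edges=edges)
    p2 = estimate_pmf(halves[1], edges=edges)
    both = p1.occupied & p2.occupied
    dev = float(np.max(np.abs(p1.free_energy[both] - p2.free_energy[both])))
    return p1, p2, dev


# --------------------------------------------------------------------------- #
# Occurrence reweighting
# --------------------------------------------------------------------------- #

def reweighted_occurrence(present: np.ndarray, weights, mask=None) -> float:
    """Unbiased occurrence of a boolean observable over (masked) pooled frames.

    ``sum(w_n present_n) / sum(w_n)`` with MBAR weights; reduces to the plain
    average when all biases are identical (uniform weights).
    """
    p = np.asarray(present, dtype=float)
    w = weights.weights if isinstance(weights, MBARResult) else np.asarray(weights, float)
    if p.shape != w.shape:
        raise ValueError("presence and weights must align to the pooled frames")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        p, w = p[mask], w[mask]
    total = w.sum()
    if total <= 0:
        raise ValueError("frame mask selects zero total weight; occurrence undefined")
    return float((w * p).sum() / total)
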