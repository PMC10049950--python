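"""Synthetic inputs for the dissociation-stability pipeline.

Everything the analysis consumes can be generated here at desk scale:

* analytic 1-D potentials along the inter-chain COM-distance collective
  variable (CV), with quadrature-exact Boltzmann references,
* overdamped-Langevin umbrella sampling on those potentials (harmonic bias
  around a ladder of window centers, reflecting CV-domain boundaries),
* annotated bead-model "Fab" structures and rigid/staged dissociation
  trajectories,
* bell-shaped bound-ensemble descriptor samples and sigmoidal
  descriptor-vs-CV dissociation traces with a designed transition point,
* cohorts of systems whose true well depths relate linearly (plus noise)
  to a melting temperature, emulating a depth <-> Tm relationship.

Only the stationary distribution of the sampler matters downstream (the
reweighting stage is estimator-based, not kinetic).  The sampler therefore
uses Metropolis-adjusted overdamped Langevin steps: the Brownian
Euler-Maruyama proposal is kept or rejected with the exact
Metropolis-Hastings ratio, so window histograms follow the Boltzmann law of
``U + bias`` exactly instead of carrying an O(dt) discretization bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import skewnorm

from .constants import EQUIL_FRACTION_DEFAULT, SPRING_DEFAULT, T_DEFAULT, kt
from .reweighting import UmbrellaWindow
from .structure import BeadStructure, BeadTrajectory, CHAIN_OF_DOMAIN, DOMAINS

__all__ = [
    "ToyPotential", "ToyFabSpec", "CohortSpec", "CohortSystem",
    "simulate_umbrella_window", "simulate_umbrella_ladder",
    "build_toy_fab", "generate_dissociation_trajectory",
    "generate_bound_ensemble", "generate_dissociation_trace",
    "generate_cohort", "boltzmann_pmf", "boltzmann_density",
]


# --------------------------------------------------------------------------- #
# Toy potentials
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ToyPotential:
    """Analytic 1-D free-energy landscape along the CV, in units of kT.

    Forms
    -----
    flat
        U = 0 everywhere.
    harmonic
        U = depth * (width * (x - r0))**2 / 2  (stiffness depth*width^2 kT/nm^2).
    morse_well
        U = depth * ((1 - exp(-width*(x - r0)))**2 - 1); the well depth is
        exactly ``depth`` and the dissociated plateau is 0.
    double_well
        U = depth * ((width*(x - r0))**2 - 1)**2; minima at r0 +/- 1/width,
        barrier of height ``depth`` at r0.
    """

    form: str = "flat"
    depth: float = 0.0          # kT
    width: float = 1.0          # 1/nm
    r0: float = 2.0             # nm
    domain: tuple = (1.6, 4.2)  # nm

    def __post_init__(self):
        if self.form not in ("flat", "harmonic", "morse_well", "double_well"):
            raise ValueError(f"unknown potential form {self.form!r}")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("domain must satisfy lo < hi")

    def energy_kt(self, x):
        """Potential in kT units, vectorized over x."""
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            return 0.5 * self.depth * (self.width * (x - self.r0)) ** 2
        if self.form == "morse_well":
            e = np.exp(-self.width * (x - self.r0))
            return self.depth * ((1.0 - e) ** 2 - 1.0)
        u = (self.width * (x - self.r0)) ** 2 - 1.0
        return self.depth * u ** 2

    def force_kt(self, x):
        """-dU/dx in kT/nm, vectorized over x."""
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            return -self.depth * self.width ** 2 * (x - self.r0)
        if self.form == "morse_well":
            e = np.exp(-self.width * (x - self.r0))
            return -2.0 * self.depth * self.width * (1.0 - e) * e
        s = self.width * (x - self.r0)
        return -4.0 * self.depth * self.width * s * (s ** 2 - 1.0)


def boltzmann_density(potential: ToyPotential, *, center: float | None = None,
                      spring_kt: float = 0.0, n_grid: int = 10001):
    """Normalized Boltzmann density of ``U + bias`` on a uniform CV grid.

    ``spring_kt`` is the harmonic bias stiffness in kT/nm^2.  Returns
    ``(grid, density)``; the density integrates to 1 over the CV domain.
    """
    lo, hi = potential.domain
    x = np.linspace(lo, hi, n_grid)
    u = potential.energy_kt(x)
    if center is not None:
        u = u + 0.5 * spring_kt * (x - center) ** 2
    u = u - u.min()
    p = np.exp(-u)
    p /= np.trapezoid(p, x)
    return x, p


def boltzmann_pmf(potential: ToyPotential, edges, temperature: float = T_DEFAULT,
                  n_grid: int = 10001):
    """Quadrature-exact binned PMF of a toy potential, in kJ/mol.

    For each bin ``F_b = -kT * ln(integral_bin exp(-U/kT))``, shifted so the
    minimum bin is 0.  Serves as the analytic reference the estimated PMF
    must converge to.
    """
    edges = np.asarray(edges, dtype=float)
    kbt = kt(temperature)
    f = np.empty(len(edges) - 1)
    for b in range(len(edges) - 1):
        x = np.linspace(edges[b], edges[b + 1], max(2, n_grid // (len(edges) - 1)))
        u = potential.energy_kt(x)
        m = u.min()
        z = np.trapezoid(np.exp(-(u - m)), x)
        f[b] = kbt * (m - math.log(z))
    return f - f.min()


# --------------------------------------------------------------------------- #
# Overdamped Langevin umbrella sampler
# --------------------------------------------------------------------------- #

def _integrate_windows(potential, centers, springs, kbt, n_steps, dt, friction,
                       rngs, stride, max_drift):
    """Metropolis-adjusted overdamped Langevin on U + harmonic bias.

    One walker per window.  Each step proposes the Euler-Maruyama move
    ``y = x + F(x) dt / gamma + sqrt(2 kT dt / gamma) xi`` and accepts it
    with the Metropolis-Hastings probability for the Gaussian proposal
    density, so the stationary distribution is the *exact* Boltzmann law of
    ``U + bias`` on the CV domain at any stable step size (proposals outside
    the domain are rejected, which truncates the law to the domain).  The
    drift is clamped at ``max_drift`` nm as a stability guard against the
    steep repulsive wall of deep wells; the clamp is part of the proposal,
    so it does not bias the sampled law.
    """
    lo, hi = potential.domain
    centers = np.asarray(centers, dtype=float)
    springs = np.broadcast_to(np.asarray(springs, dtype=float), centers.shape).copy()
    x = np.clip(centers.copy(), lo, hi)
    mob = dt / friction
    two_sig2 = 4.0 * kbt * dt / friction   # 2 sigma^2 of the proposal

    def energy(z):
        return kbt * potential.energy_kt(z) + 0.5 * springs * (z - centers) ** 2

    def drift(z):
        f = kbt * potential.force_kt(z) - springs * (z - centers)
        if not np.all(np.isfinite(f)):
            bad = int(np.flatnonzero(~np.isfinite(f))[0])
            raise FloatingPointError(
                f"non-finite force in window {bad}, x={z[bad]!r}")
        return np.clip(f * mob, -max_drift, max_drift)

    n_rec = n_steps // stride
    out = np.empty((n_rec, len(centers)))
    # per-window noise streams keep each window bit-reproducible on its own
    noise = np.stack([r.standard_normal(n_steps) for r in rngs], axis=1)
    logu = np.log(np.stack([r.uniform(1e-300, 1.0, n_steps) for r in rngs],
                           axis=1))
    sigma = math.sqrt(2.0 * kbt * dt / friction)
    u_x = energy(x)
    d_x = drift(x)
    for i in range(n_steps):
        y = x + d_x + sigma * noise[i]
        inside = (y >= lo) & (y <= hi)
        y_safe = np.where(inside, y, x)
        u_y = energy(y_safe)
        d_y = drift(y_safe)
        logr = (-(u_y - u_x) / kbt
                - ((x - y_safe - d_y) ** 2 - (y_safe - x - d_x) ** 2) / two_sig2)
        accept = inside & (logu[i] < logr)
        x = np.where(accept, y_safe, x)
        u_x = np.where(accept, u_y, u_x)
        d_x = np.where(accept, d_y, d_x)
        if (i + 1) % stride == 0:
            out[(i + 1) // stride - 1] = x
    return out


def _check_sampler_args(potential, center, spring, n_steps, dt, friction):
    lo, hi = potential.domain
    if spring <= 0:
        raise ValueError("spring constant must be positive")
    if friction <= 0:
        raise ValueError("friction must be positive")
    if n_steps < 1000:
        raise ValueError("n_steps must be at least 1000")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not lo <= center <= hi:
        raise ValueError(f"window center {center} outside CV domain [{lo}, {hi}]")


def simulate_umbrella_window(potential: ToyPotential, center: float,
                             spring: float = SPRING_DEFAULT,
                             kT: float = kt(T_DEFAULT),
                             n_steps: int = 50_000, dt: float = 0.002,
                             friction: float = 50.0, seed: int = 0,
                             stride: int = 1,
                             equil_fraction: float = EQUIL_FRACTION_DEFAULT,
                             index: int = 0, max_drift: float = 0.1) -> UmbrellaWindow:
    """Sample one umbrella window by Metropolis-adjusted Langevin dynamics.

    Parameters use kJ/mol energies, nm lengths and ps times: ``spring`` in
    kJ mol^-1 nm^-2, ``kT`` in kJ/mol, ``friction`` in kJ mol^-1 ps nm^-2.
    Samples stay inside the CV domain (out-of-domain proposals are
    rejected).  Every ``stride``-th step is recorded; the first
    ``equil_fraction`` of the recorded series is split off as equilibration
    (``n_discarded``).
    """
    _check_sampler_args(potential, center, spring, n_steps, dt, friction)
    rng = np.random.default_rng(seed)
    rec = _integrate_windows(potential, [center], [spring], kT, n_steps, dt,
                             friction, [rng], stride, max_drift)[:, 0]
    n_disc = int(len(rec) * equil_fraction)
    return UmbrellaWindow(index=index, center=float(center), spring=float(spring),
                          temperature=kT / kt(1.0), samples=rec[n_disc:],
                          n_discarded=n_disc)


def simulate_umbrella_ladder(potential: ToyPotential, centers,
                             spring: float = SPRING_DEFAULT,
                             kT: float = kt(T_DEFAULT),
                             n_steps: int = 50_000, dt: float = 0.002,
                             friction: float = 50.0, seed: int = 0,
                             stride: int = 1,
                             equil_fraction: float = EQUIL_FRACTION_DEFAULT,
                             max_drift: float = 0.1) -> list[UmbrellaWindow]:
    """Sample a whole window ladder in one vectorized sweep.

    The root seed is split into one independent stream per window
    (``numpy.random.SeedSequence.spawn``), recorded in the window index order.
    """
    centers = np.asarray(centers, dtype=float)
    for c in centers:
        _check_sampler_args(potential, c, spring, n_steps, dt, friction)
    seqs = np.random.SeedSequence(seed).spawn(len(centers))
    rngs = [np.random.default_rng(s) for s in seqs]
    rec = _integrate_windows(potential, centers, spring, kT, n_steps, dt,
                             friction, rngs, stride, max_drift)
    n_disc = int(rec.shape[0] * equil_fraction)
    return [
        UmbrellaWindow(index=k, center=float(centers[k]), spring=float(spring),
                       temperature=kT / kt(1.0), samples=rec[n_disc:, k],
                       n_discarded=n_disc)
        for k in range(len(centers))
    ]


# --------------------------------------------------------------------------- #
# Toy Fab structures
# --------------------------------------------------------------------------- #

# chemistry of the default interface pairs: H-side class, L-side class,
# H-side moiety, L-side moiety -> covers all hydrogen-bond flavours, a salt
# bridge in both charge orders and a hydrophobic pair
_PAIR_CHEMISTRY = [
    ("donor", "acceptor", "bb", "bb"),
    ("acceptor", "donor", "sc", "bb"),
    ("pos", "neg", "sc", "bb"),
    ("neg", "pos", "bb", "sc"),
    ("phobic", "phobic", "sc", "bb"),
    ("donor", "acceptor", "sc", "sc"),
]

_GROUP_CYCLE = {
    "VH": ["h_C", "h_D", "h_E", "CDR-H1", "CDR-H2"],
    "VL": ["l_C", "l_D", "CDR-L1", "CDR-L2"],
    "CH1": ["h_A", "h_B", "h_AB", "h_DE"],
    "CL": ["l_A", "l_B", "l_G", "l_DE"],
}
_CONTACT_GROUP = {"VH": "h_HI", "VL": "l_GH", "CH1": "h_G", "CL": "l_AB"}


@dataclass
class ToyFabSpec:
    """Recipe for a four-domain bead Fab surrogate.

    ``native_pairs`` lists inter-chain bead index pairs (global indices, H
    chain first in the global ordering VH, CH1, VL, CL) that the builder must
    realise within ``native_cutoff``; ``None`` selects the default pattern of
    ``n_contacts`` pairs per interface (VH-VL and CH1-CL).
    """

    beads_per_domain: int = 20
    centroids: dict = field(default_factory=lambda: {
        "VH": (0.0, 1.5, 0.0), "CH1": (0.0, 0.0, 0.0),
        "VL": (1.9, 1.5, 0.0), "CL": (1.9, 0.0, 0.0)})
    native_pairs: list | None = None
    n_contacts: int = 6
    native_cutoff: float = 0.45    # nm
    contact_gap: float = 0.30      # nm, inside the H-bond distance criterion
    blob_sigma: float = 0.35       # nm, scatter of non-interface beads
    group_map: dict | None = None  # optional bead index -> group override
    seed: int = 0

    def __post_init__(self):
        if self.beads_per_domain < 1:
            raise ValueError("beads_per_domain must be >= 1")
        if not 0 < self.contact_gap < self.native_cutoff:
            raise ValueError("contact_gap must lie in (0, native_cutoff)")
        if self.native_pairs is None and 2 * self.n_contacts > self.beads_per_domain:
            raise ValueError("n_contacts cannot exceed beads_per_domain // 2")


def _domain_layout(spec: ToyFabSpec):
    """Global bead index ranges per domain, ordering VH, CH1, VL, CL."""
    n = spec.beads_per_domain
    order = ("VH", "CH1", "VL", "CL")
    start = {d: i * n for i, d in enumerate(order)}
    return order, start, n


def build_toy_fab(spec: ToyFabSpec) -> BeadStructure:
    """Deterministically build an annotated bead Fab from its spec.

    Interface beads of each native pair are placed opposite each other across
    the midplane of their domains' centroids at ``contact_gap`` separation;
    the remaining beads scatter around the domain centroid.  Listed native
    pairs must be inter-chain and realizable, otherwise a ``ValueError``
    names the offending pair.
    """
    order, start, n = _domain_layout(spec)
    n_total = 4 * n
    rng = np.random.default_rng(spec.seed)

    domain = np.empty(n_total, dtype="U4")
    chain = np.empty(n_total, dtype="U1")
    for d in order:
        sl = slice(start[d], start[d] + n)
        domain[sl] = d
        chain[sl] = CHAIN_OF_DOMAIN[d]

    if spec.native_pairs is None:
        # every other residue, so each interface bead's sequence neighbour sits
        # back in the domain blob and the donor-alignment surrogate can pass
        pairs = [(start["VH"] + 2 * k, start["VL"] + 2 * k)
                 for k in range(spec.n_contacts)]
        pairs += [(start["CH1"] + 2 * k, start["CL"] + 2 * k)
                  for k in range(spec.n_contacts)]
    else:
        pairs = [tuple(int(v) for v in p) for p in spec.native_pairs]
    for i, j in pairs:
        if chain[i] == chain[j]:
            raise ValueError(f"native pair ({i}, {j}) is not inter-chain "
                             f"(both on chain {chain[i]})")

    centroids = {d: np.asarray(spec.centroids[d], dtype=float) for d in DOMAINS}
    coords = np.empty((n_total, 3))
    for d in order:
        sl = slice(start[d], start[d] + n)
        coords[sl] = centroids[d] + rng.normal(0.0, spec.blob_sigma, (n, 3))

    placed = np.zeros(n_total, dtype=bool)
    half = spec.contact_gap / 2.0
    for i, j in pairs:
        ci, cj = centroids[domain[i]], centroids[domain[j]]
        axis = cj - ci
        axis = axis / np.linalg.norm(axis)
        mid = 0.5 * (ci + cj)
        # jitter perpendicular to the interface axis, shared by the pair
        perp = rng.normal(0.0, 0.12, 3)
        perp -= axis * (perp @ axis)
        if placed[i] and not placed[j]:
            coords[j] = coords[i] + axis * spec.contact_gap
        elif placed[j] and not placed[i]:
            coords[i] = coords[j] - axis * spec.contact_gap
        elif not placed[i] and not placed[j]:
            coords[i] = mid - axis * half + perp
            coords[j] = mid + axis * half + perp
        placed[i] = placed[j] = True

    for i, j in pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > spec.native_cutoff:
            raise ValueError(
                f"native pair ({i}, {j}) unrealizable: built distance "
                f"{d:.3f} nm exceeds cutoff {spec.native_cutoff} nm")

    group = np.empty(n_total, dtype="U16")
    bclass = np.full(n_total, "none", dtype="U16")
    moiety = np.empty(n_total, dtype="U2")
    for d in order:
        cyc = _GROUP_CYCLE[d]
        for k in range(n):
            idx = start[d] + k
            group[idx] = cyc[k % len(cyc)]
            moiety[idx] = "bb" if k % 2 == 0 else "sc"
            bclass[idx] = ("donor", "acceptor", "phobic", "none")[k % 4]
    for p, (i, j) in enumerate(pairs):
        ch, cl, mh, ml = _PAIR_CHEMISTRY[p % len(_PAIR_CHEMISTRY)]
        a, b = (i, j) if chain[i] == "H" else (j, i)
        group[a] = _CONTACT_GROUP.get(domain[a], group[a])
        group[b] = _CONTACT_GROUP.get(domain[b], group[b])
        bclass[a], bclass[b] = ch, cl
        moiety[a], moiety[b] = mh, ml
    if spec.group_map:
        for idx, g in spec.group_map.items():
            group[int(idx)] = g

    res_id = np.empty(n_total, dtype=int)
    for c in ("H", "L"):
        sel = np.flatnonzero(chain == c)
        res_id[sel] = np.arange(1, len(sel) + 1)

    return BeadStructure(coords=coords, chain_id=chain, res_id=res_id,
                         domain=domain, group=group, bead_class=bclass,
                         moiety=moiety)


def generate_dissociation_trajectory(structure: BeadStructure, path: str = "rigid",
                                     n_frames: int = 51, noise_sigma: float = 0.0,
                                     seed: int = 0, final_offset: float = 2.25,
                                     dt_ps: float = 1.0) -> BeadTrajectory:
    """Pull the L chain off the H chain along the inter-chain COM axis.

    ``path`` selects which interface opens first: ``fv_first`` delays the CL
    displacement until halfway through, ``ch1cl_first`` delays VL, ``rigid``
    moves the whole L chain synchronously (linear COM-distance schedule).
    Frame 0 is the bound structure; Gaussian coordinate noise (``noise_sigma``
    nm) is added to every later frame.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if path not in ("rigid", "fv_first", "ch1cl_first"):
        raise ValueError(f"unknown path {path!r}")
    rng = np.random.default_rng(seed)
    h = structure.select(chain="H")
    l = structure.select(chain="L")
    m = structure.masses
    com_h = np.average(structure.coords[h], axis=0, weights=m[h])
    com_l = np.average(structure.coords[l], axis=0, weights=m[l])
    axis = com_l - com_h
    axis = axis / np.linalg.norm(axis)

    frames = np.arange(n_frames, dtype=float)
    full = frames / (n_frames - 1)
    delay = (n_frames - 1) // 2
    delayed = np.clip((frames - delay) / (n_frames - 1 - delay), 0.0, 1.0)
    if path == "rigid":
        s_vl, s_cl = full, full
    elif path == "fv_first":
        s_vl, s_cl = full, delayed
    else:
        s_vl, s_cl = delayed, full

    vl = structure.select(domain="VL")
    cl = structure.select(domain="CL")
    coords = np.repeat(structure.coords[None, :, :], n_frames, axis=0)
    coords[:, vl, :] += final_offset * s_vl[:, None, None] * axis
    coords[:, cl, :] += final_offset * s_cl[:, None, None] * axis
    if noise_sigma > 0:
        coords[1:] += rng.normal(0.0, noise_sigma, coords[1:].shape)
    return BeadTrajectory(topology=structure, coords=coords, dt_ps=dt_ps)


# --------------------------------------------------------------------------- #
# Descriptor-level generators
# --------------------------------------------------------------------------- #

def _skewnorm_mode_offset(a: float) -> float:
    """Mode of the standard skew-normal with shape ``a`` (numeric)."""
    if a == 0:
        return 0.0
    res = minimize_scalar(lambda z: -skewnorm.pdf(z, a), bounds=(-3.0, 3.0),
                          method="bounded")
    return float(res.x)


def _bell_samples(rng, loc, scale, skew, n):
    """Skew-normal samples whose distribution mode sits at ``loc``."""
    if scale <= 0:
        raise ValueError("descriptor scale must be positive")
    z = skewnorm.rvs(skew, size=n, random_state=rng)
    return loc + scale * (z - _skewnorm_mode_offset(skew))


def generate_bound_ensemble(q=(0.9, 0.03, -4.0), d1=(2.0, 0.05, 4.0),
                            d2=(2.0, 0.05, 4.0), cv=(1.75, 0.03, 0.0),
                            sasa=(60.0, 1.0, 0.0), n_frames: int = 20_000,
                            dt_ps: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Bell-shaped bound-state descriptor samples, one row per frame.

    Each descriptor is given as ``(mode, scale, skew)``; samples are drawn
    from a skew-normal re-centred so its mode equals the requested location
    (q is additionally clipped to [0, 1]).  Returns a descriptor-trace
    DataFrame with columns frame, time_ps, cv_nm, q, d1_nm, d2_nm, sasa_nm2.
    """
    rng = np.random.default_rng(seed)
    qs = np.clip(_bell_samples(rng, *q, n_frames), 0.0, 1.0)
    return pd.DataFrame({
        "frame": np.arange(n_frames),
        "time_ps": np.arange(n_frames) * dt_ps,
        "cv_nm": _bell_samples(rng, *cv, n_frames),
        "q": qs,
        "d1_nm": _bell_samples(rng, *d1, n_frames),
        "d2_nm": _bell_samples(rng, *d2, n_frames),
        "sasa_nm2": _bell_samples(rng, *sasa, n_frames),
    })


def generate_dissociation_trace(n_frames: int = 600, cv_start: float = 1.7,
                                cv_end: float = 4.0, transition_cv: float = 2.3,
                                unbind_offset: float = 0.6,
                                steepness: float = 30.0,
                                q_bound: float = 0.9, q_mid_frac: float = 0.35,
                                d1_bound: float = 2.0, d2_bound: float = 2.0,
                                d_rise: float = 1.5, sasa_bound: float = 60.0,
                                sasa_rise: float = 25.0,
                                sasa_steepness: float = 10.0,
                                noise=(0.01, 0.01, 0.3), dt_ps: float = 1.0,
                                ch1cl_dissociates: bool = True,
                                seed: int = 0) -> pd.DataFrame:
    """Descriptor-vs-CV dissociation trace with a designed transition point.

    Frames are ordered by increasing CV (the concatenation convention for
    umbrella runs).  q decays in two stages: a partial loss of contacts at
    ``transition_cv`` (the designed bound -> encounter point) and the loss of
    the remainder ``unbind_offset`` nm later (encounter -> unbound), where
    SASA also plateaus.  d1/d2 rise sigmoidally at the transition; with
    ``ch1cl_dissociates=False`` d2 stays bound, emulating systems whose
    constant-domain interface never opens inside the sampled CV range.
    """
    rng = np.random.default_rng(seed)
    cv = np.linspace(cv_start, cv_end, n_frames)
    m1, m2 = transition_cv, transition_cv + unbind_offset
    sq, sd, ss = noise

    stage1 = expit(-steepness * (cv - m1))
    stage2 = expit(-sasa_steepness * (cv - m2))
    q = q_bound * ((1.0 - q_mid_frac) * stage1 + q_mid_frac * stage2)
    d1 = d1_bound + d_rise * expit(steepness * (cv - m1))
    if ch1cl_dissociates:
        d2 = d2_bound + d_rise * expit(steepness * (cv - m1 - 0.05))
    else:
        d2 = np.full_like(cv, d2_bound)
    sasa = sasa_bound + sasa_rise * expit(sasa_steepness * (cv - m2))

    q = np.clip(q + rng.normal(0.0, sq, n_frames), 0.0, 1.0)
    d1 = d1 + rng.normal(0.0, sd, n_frames)
    d2 = d2 + rng.normal(0.0, sd, n_frames)
    sasa = sasa + rng.normal(0.0, ss, n_frames)
    return pd.DataFrame({
        "frame": np.arange(n_frames), "time_ps": np.arange(n_frames) * dt_ps,
        "cv_nm": cv, "q": q, "d1_nm": d1, "d2_nm": d2, "sasa_nm2": sasa,
    })


# --------------------------------------------------------------------------- #
# Cohorts
# --------------------------------------------------------------------------- #

@dataclass
class CohortSpec:
    """A family of systems whose Tm depends linearly on true well depth.

    ``Tm_i = alpha + beta * D_i + Normal(0, sigma)``.  Defaults give 16
    systems with depths uniform on 2..10 kT and a population depth <-> Tm
    correlation of about 0.8 (sigma = 3.5 K against beta^2 Var(D) ~ 21 K^2).
    """

    n_systems: int = 16
    depths: list | None = None       # explicit depths in kT, or None
    depth_range: tuple = (2.0, 10.0)  # kT, uniform sampling range
    alpha: float = 340.0             # K
    beta: float = 2.0                # K per kT
    sigma: float = 3.5               # K
    morse_width: float = 6.0         # 1/nm
    morse_r0: float = 2.0            # nm
    domain: tuple = (1.6, 4.2)       # nm
    seed: int = 0

    def __post_init__(self):
        if self.n_systems < 2:
            raise ValueError("n_systems must be >= 2")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.depths is not None:
            if len(self.depths) != self.n_systems:
                raise ValueError("depths length must equal n_systems")
            if any(d <= 0 for d in self.depths):
                raise ValueError("depths must be strictly positive")


@dataclass
class CohortSystem:
    system_id: str
    potential: ToyPotential
    true_depth: float   # kT
    tm: float           # K
    seed: int


def generate_cohort(spec: CohortSpec) -> list[CohortSystem]:
    """Draw a cohort of morse-well systems with depth-linked Tm values."""
    rng = np.random.default_rng(spec.seed)
    if spec.depths is not None:
        depths = np.asarray(spec.depths, dtype=float)
    else:
        lo, hi = spec.depth_range
        depths = rng.uniform(lo, hi, spec.n_systems)
    noise = rng.normal(0.0, spec.sigma, spec.n_systems) if spec.sigma > 0 \
        else np.zeros(spec.n_systems)
    tm = spec.alpha + spec.beta * depths + noise
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_systems)
    systems = []
    for i in range(spec.n_systems):
        pot = ToyPotential(form="morse_well", depth=float(depths[i]),
                           width=spec.morse_width, r0=spec.morse_r0,
                           domain=spec.domain)
        systems.append(CohortSystem(
            system_id=f"sys{i:02d}", potential=pot,
            true_depth=float(depths[i]), tm=float(tm[i]),
            seed=int(child_seeds[i].generate_state(1)[0] % (2 ** 31))))
    return systems


def cohort_manifest(systems: list[CohortSystem]) -> pd.DataFrame:
    """Cohort table with columns system_id, true_depth, tm."""
    return pd.DataFrame({
        "system_id": [s.system_id for s in systems],
        "true_depth": [s.true_depth for s in systems],
        "tm": [s.tm for s in systems],
    })
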