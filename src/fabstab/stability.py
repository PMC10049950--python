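"""Interface-stability metric: PMF well depth versus melting temperature.

The PMF along the inter-chain COM distance is truncated at the detected
bound -> encounter-complex transition; the stability metric of a system is
the depth of the global minimum of the truncated profile, measured against
the encounter-side plateau (mean of the last few occupied bins at or below
the transition CV).  Across a cohort of systems the depth is correlated
against experimentally styled melting temperatures with a Pearson
coefficient and a seeded bootstrap confidence interval.

``run_system`` orchestrates the whole desk-scale pipeline for one system:
bound-ensemble state-model fit, dissociation trace, transition detection,
umbrella-ladder simulation, MBAR reweighting, PMF and depth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .constants import SPRING_DEFAULT, T_DEFAULT, kt
from .reweighting import (PMFProfile, make_window_ladder, pmf_uncertainty,
                          pmf_from_weights, solve_windows)
from .statemodel import BoundStateModel, TransitionReport, detect_transitions

__all__ = [
    "SystemStability", "CorrelationResult", "SystemConfig",
    "energy_depth", "correlate_depth_tm", "run_system", "run_cohort",
]


@dataclass
class SystemStability:
    """One system's stability readout."""

    system_id: str
    depth: float                 # kJ/mol, >= 0
    depth_err: float             # kJ/mol
    depth_kt: float              # depth in kT at the run temperature
    transition_cv: float         # nm
    tm: float | None             # K, experimental input
    fv_dissociated: bool = True
    ch1cl_dissociated: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class CorrelationResult:
    """Pearson correlation of depth against Tm over a cohort."""

    r: float
    n: int
    pairs: pd.DataFrame          # system_id, depth, tm
    ci_low: float
    ci_high: float
    n_boot: int


def energy_depth(pmf: PMFProfile, transition_cv: float,
                 n_ref_bins: int = 3) -> tuple[float, float]:
    """Depth of the global PMF minimum up to the transition point.

    ``depth = F_ref - F_min`` over occupied bins whose centers lie at or
    below ``transition_cv``; the reference level ``F_ref`` is the mean of
    the last ``n_ref_bins`` occupied bins of that range (the encounter-side
    plateau).  The uncertainty combines the minimum-bin and reference-bin
    sigmas in quadrature when the profile carries uncertainties.
    """
    if transition_cv is None:
        raise ValueError(
            "no bound->encounter transition supplied; pass the profile's "
            "upper edge explicitly to request the full-range fallback")
    centers = pmf.centers
    if not pmf.edges[0] <= transition_cv <= pmf.edges[-1]:
        raise ValueError(f"transition CV {transition_cv} outside PMF range")
    sel = np.flatnonzero(pmf.occupied & (centers <= transition_cv))
    if sel.size < 2:
        raise ValueError("fewer than 2 occupied bins at or below the transition")
    F = pmf.free_energy
    i_min = sel[np.argmin(F[sel])]
    ref_bins = sel[-n_ref_bins:]
    depth = float(np.mean(F[ref_bins]) - F[i_min])
    if pmf.uncertainty is not None:
        sig = pmf.uncertainty
        err = float(math.sqrt(sig[i_min] ** 2 + np.mean(sig[ref_bins] ** 2) / len(ref_bins)))
    else:
        err = 0.0
    return depth, err


def correlate_depth_tm(systems: list[SystemStability], n_boot: int = 1000,
                       seed: int = 0, include_flagged: bool = False
                       ) -> CorrelationResult:
    """Sample Pearson correlation of (depth, Tm) with a bootstrap CI.

    Systems lacking a Tm are dropped; systems that did not dissociate in
    both regions are excluded unless ``include_flagged``.
    """
    kept = [s for s in systems if s.tm is not None
            and (include_flagged or (s.fv_dissociated and s.ch1cl_dissociated))]
    if len(kept) < 3:
        raise ValueError("need at least 3 systems with Tm for a correlation")
    depth = np.array([s.depth for s in kept])
    tm = np.array([s.tm for s in kept])
    if np.ptp(depth) == 0 or np.ptp(tm) == 0:
        raise ValueError("zero variance in depth or Tm; correlation undefined")
    r = float(pearsonr(depth, tm).statistic)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(kept), len(kept))
        if np.ptp(depth[idx]) == 0 or np.ptp(tm[idx]) == 0:
            continue
        boots.append(pearsonr(depth[idx], tm[idx]).statistic)
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    pairs = pd.DataFrame({"system_id": [s.system_id for s in kept],
                          "depth": depth, "tm": tm})
    return CorrelationResult(r=r, n=len(kept), pairs=pairs,
                             ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


# --------------------------------------------------------------------------- #
# Orchestration
# --------------------------------------------------------------------------- #

@dataclass
class SystemConfig:
    """Every decided parameter of a single-system pipeline run."""

    system_id: str = "sys00"
    potential: object = None          # ToyPotential
    tm: float | None = None
    seed: int = 0
    # umbrella sampling
    ladder_kwargs: dict = field(default_factory=dict)
    spring: float = SPRING_DEFAULT
    temperature: float = T_DEFAULT
    n_steps: int = 30_000
    dt: float = 0.002
    friction: float = 50.0
    stride: int = 10
    equil_fraction: float = 0.10
    # PMF
    bin_width: float = 0.05
    n_boot: int = 0                   # 0 skips the bootstrap uncertainty
    # state model
    transition_cv: float | None = None  # explicit override; None -> detect
    trace_kwargs: dict = field(default_factory=dict)
    bound_kwargs: dict = field(default_factory=dict)
    theta_b: float = 0.01
    theta_u: float = 0.01
    dwell: int = 10
    n_ref_bins: int = 3
    outdir: str | None = None

    def validate(self):
        if self.potential is None:
            raise ValueError("config needs a potential")
        if self.n_steps < 1000 or self.stride < 1:
            raise ValueError("invalid sampling parameters")
        return self


def run_system(config: SystemConfig):
    """End-to-end pipeline for one system.

    Returns ``(SystemStability, TransitionReport, PMFProfile)``.  With
    ``config.outdir`` set, all intermediate artifacts (window CSVs, traces,
    state series, PMF, report, run log) are written there.
    """
    from . import io as fio
    from .synthetic import (generate_bound_ensemble, generate_dissociation_trace,
                            simulate_umbrella_ladder)

    config.validate()
    seq = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seq]
    kbt = kt(config.temperature)

    # 1. bound-state model from a bound descriptor ensemble
    bound = generate_bound_ensemble(seed=seeds[0], **config.bound_kwargs)
    model = BoundStateModel.fit(bound, theta_b=config.theta_b, dwell=config.dwell)

    # 2. dissociation trace -> transitions
    trace = generate_dissociation_trace(seed=seeds[1], **config.trace_kwargs)
    report = detect_transitions(trace, model, theta_u=config.theta_u)

    # 3. umbrella ladder -> MBAR -> PMF
    centers = make_window_ladder(**config.ladder_kwargs)
    windows = simulate_umbrella_ladder(
        config.potential, centers, spring=config.spring, kT=kbt,
        n_steps=config.n_steps, dt=config.dt, friction=config.friction,
        seed=seeds[2], stride=config.stride,
        equil_fraction=config.equil_fraction)
    result, x_pooled = solve_windows(windows)
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    edges = np.arange(lo, hi + config.bin_width, config.bin_width)
    pmf = pmf_from_weights(x_pooled, result, edges, temperature=config.temperature)
    if config.n_boot >= 20:
        pmf.uncertainty = pmf_uncertainty(windows, edges, n_boot=config.n_boot,
                                          seed=seeds[2])

    # 4. depth at the detected (or overridden) transition
    if config.transition_cv is not None:
        t_cv = config.transition_cv
    elif report.bound_encounter is not None:
        t_cv = report.bound_encounter[1]
    else:
        raise ValueError(
            f"system {config.system_id}: no bound->encounter transition "
            "detected; set config.transition_cv for an explicit fallback")
    t_cv = float(np.clip(t_cv, pmf.edges[0], pmf.edges[-1]))
    depth, err = energy_depth(pmf, t_cv, n_ref_bins=config.n_ref_bins)

    stab = SystemStability(
        system_id=config.system_id, depth=depth, depth_err=err,
        depth_kt=depth / kbt, transition_cv=t_cv, tm=config.tm,
        fv_dissociated=report.fv_dissociated,
        ch1cl_dissociated=report.ch1cl_dissociated)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_windows(windows, out / "windows",
                          meta={"spring": config.spring,
                                "temperature": config.temperature,
                                "equil_fraction": config.equil_fraction,
                                "seed": seeds[2]})
        bound.to_csv(out / "bound_trace.csv", index=False)
        trace.to_csv(out / "dissociation_trace.csv", index=False)
        pmf.to_dataframe().to_csv(out / "pmf.csv", index=False)
        report.to_json(out / "transitions.json")
        stab.to_json(out / "stability.json")
        log = {k: v for k, v in asdict(config).items() if k != "potential"}
        log["potential"] = asdict(config.potential)
        log["derived_seeds"] = seeds
        log["mbar_iterations"] = result.iterations
        log["mbar_converged"] = bool(result.converged)
        (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return stab, report, pmf


def run_cohort(systems, base_config: SystemConfig | None = None,
               transition_cv: float | None = None, n_boot_corr: int = 1000,
               corr_seed: int = 0):
    """Run the pipeline over a cohort and correlate depth against Tm.

    ``systems`` is the output of :func:`fabstab.synthetic.generate_cohort`.
    Returns ``(stabilities, CorrelationResult | None)``; the correlation is
    skipped (None) when fewer than three systems carry a Tm.
    """
    import dataclasses

    base = base_config or SystemConfig()
    stabs = []
    for sys in systems:
        cfg = dataclasses.replace(
            base, system_id=sys.system_id, potential=sys.potential,
            tm=sys.tm, seed=sys.seed)
        if transition_cv is not None:
            cfg.transition_cv = transition_cv
        stab, _, _ = run_system(cfg)
        stabs.append(stab)
    usable = [s for s in stabs if s.tm is not None]
    corr = None
    if len(usable) >= 3:
        corr = correlate_depth_tm(stabs, n_boot=n_boot_corr, seed=corr_seed)
    return stabs, corr


def plot_depth_vs_tm(corr: CorrelationResult, path: str | Path) -> None:
    """Scatter of cohort depths against melting temperatures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(corr.pairs["depth"], corr.pairs["tm"], c="tab:blue")
    ax.set_xlabel("energy depth (kJ/mol)")
    ax.set_ylabel("melting temperature (K)")
    ax.set_title(f"Pearson r = {corr.r:.2f} (n = {corr.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
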