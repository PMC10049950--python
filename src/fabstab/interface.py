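"""Grouped interface-contact occurrence and inter-domain orientation.

Residue-pair contacts are aggregated to loop/strand group pairs (logical OR
over member pairs per frame), reweighted with MBAR weights inside state
windows (a short snapshot from the start of the run for the bound state and
from the bound -> encounter transition for the encounter complex), and
filtered at a display threshold (strictly greater than, 0.3 by default).

Domain orientation uses simplified principal-axis frames: the origin is the
bead centroid and the axes are the covariance eigenvectors, sign-fixed
toward designated reference beads.  Because these frames are a convention
of this package (not consensus-structure reference planes), absolute angle
values are not comparable with antibody-community tools — only shifts and
standard deviations along a trajectory are meaningful.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import ContactEvents
from .reweighting import MBARResult, reweighted_occurrence
from .statemodel import TransitionReport

__all__ = [
    "OccurrenceMatrix", "OrientationAngles", "DomainFrame", "GroupedContacts",
    "group_contacts", "state_window_occurrence", "occurrence_filter",
    "domain_frame", "interdomain_orientation", "orientation_series",
    "orientation_shift", "write_flareplot_json",
]

STATE_TAGS = ("bound", "bound_encounter_transition", "encounter")


# --------------------------------------------------------------------------- #
# Grouped occurrence
# --------------------------------------------------------------------------- #

@dataclass
class GroupedContacts:
    """Presence bits per unordered group pair (OR over member residue pairs)."""

    pairs: list                  # [(groupA, groupB), ...]
    present: np.ndarray          # (n_pairs, n_frames) bool


def group_contacts(events: ContactEvents) -> GroupedContacts:
    """Aggregate residue-pair contacts to group pairs by logical OR.

    Every contacting residue must carry a group label; the pair label is
    order-independent (sorted).  A group pair is present in a frame iff any
    member residue-pair contact (of any type) is present.
    """
    keys = {}
    rows = []
    for e, row in enumerate(events.meta.itertuples(index=False)):
        for g, ch, res in ((row.groupA, row.chainA, row.resA),
                           (row.groupB, row.chainB, row.resB)):
            if not g or g == "none":
                raise ValueError(f"residue {ch}:{res} has no group label")
        pair = tuple(sorted((row.groupA, row.groupB)))
        keys.setdefault(pair, []).append(e)
    pairs = sorted(keys)
    present = np.zeros((len(pairs), events.n_frames), dtype=bool)
    for i, p in enumerate(pairs):
        present[i] = events.present[keys[p]].any(axis=0)
    return GroupedContacts(pairs=pairs, present=present)


@dataclass
class OccurrenceMatrix:
    """Reweighted contact occurrence per (group or residue) pair and state."""

    labels: list                 # unique axis labels, e.g. ("h_HI", "l_GH")
    values: np.ndarray           # in [0, 1]
    state: str                   # one of STATE_TAGS

    def __post_init__(self):
        if self.state not in STATE_TAGS:
            raise ValueError(f"unknown state tag {self.state!r}")
        if len(set(map(tuple, self.labels))) != len(self.labels):
            raise ValueError("axis labels must be unique")
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("occurrence values must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "groupA": [l[0] for l in self.labels],
            "groupB": [l[1] for l in self.labels],
            "state": self.state, "occurrence": self.values,
        })


def state_window_occurrence(grouped: GroupedContacts, weights,
                            report: TransitionReport, span_frames: int,
                            states=("bound", "bound_encounter_transition")
                            ) -> dict[str, OccurrenceMatrix]:
    """Reweighted occurrence inside per-state snapshot windows.

    The bound window is ``[0, span)``; the transition window starts at the
    bound -> encounter frame.  Windows reaching past the trajectory end are
    truncated with a warning; a span below one frame is rejected.
    """
    if span_frames < 1:
        raise ValueError("span must map to at least one frame")
    n_frames = grouped.present.shape[1]
    w = weights.weights if isinstance(weights, MBARResult) else np.asarray(weights, float)
    if w.shape != (n_frames,):
        raise ValueError("weights must align with the contact frames")
    out = {}
    for state in states:
        if state == "bound":
            start = 0
        else:
            if report.bound_encounter is None:
                raise ValueError(f"state {state!r} requires a detected transition")
            start = int(report.bound_encounter[0])
        stop = start + span_frames
        if stop > n_frames:
            warnings.warn(f"{state} window truncated at trajectory end")
            stop = n_frames
        mask = np.zeros(n_frames, dtype=bool)
        mask[start:stop] = True
        vals = [reweighted_occurrence(grouped.present[i], w, mask)
                for i in range(len(grouped.pairs))]
        out[state] = OccurrenceMatrix(labels=list(grouped.pairs),
                                      values=np.array(vals), state=state)
    return out


def occurrence_filter(matrix: OccurrenceMatrix,
                      threshold: float = 0.3) -> OccurrenceMatrix:
    """Keep entries with occurrence strictly greater than the threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    keep = matrix.values > threshold
    return OccurrenceMatrix(labels=[l for l, k in zip(matrix.labels, keep) if k],
                            values=matrix.values[keep], state=matrix.state)


def write_flareplot_json(matrices: dict[str, OccurrenceMatrix],
                         path: str | Path) -> None:
    """Flareplot-ready JSON: nodes are groups, edges carry occurrences."""
    nodes = sorted({g for m in matrices.values() for pair in m.labels for g in pair})
    edges = [{"groupA": a, "groupB": b, "state": m.state, "occurrence": float(v)}
             for m in matrices.values() for (a, b), v in zip(m.labels, m.values)]
    Path(path).write_text(json.dumps({"nodes": nodes, "edges": edges}, indent=1))


# --------------------------------------------------------------------------- #
# Domain frames and orientation angles
# --------------------------------------------------------------------------- #

@dataclass
class DomainFrame:
    origin: np.ndarray           # (3,)
    axes: np.ndarray             # (3, 3) rows = axis1..3, right-handed


def domain_frame(coords: np.ndarray, ref_primary: int = 0,
                 ref_secondary: int = -1) -> DomainFrame:
    """Principal-axis frame of a bead cloud.

    Axes are covariance eigenvectors ordered by decreasing variance; axis 1
    and 2 signs point toward the designated reference beads, axis 3 closes
    a right-handed triad.  Degenerate (collinear) clouds are rejected.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 beads")
    origin = coords.mean(axis=0)
    cen = coords - origin
    cov = cen.T @ cen / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] < 1e-12 * max(evals[0], 1e-30):
        raise ValueError("degenerate (collinear) bead cloud")
    a1, a2 = evecs[:, 0], evecs[:, 1]
    for i, (axis, ref) in enumerate(((a1, ref_primary), (a2, ref_secondary))):
        v = cen[ref]
        if axis @ v < 0:
            axis *= -1.0
    a3 = np.cross(a1, a2)
    return DomainFrame(origin=origin, axes=np.vstack([a1, a2, a3]))


@dataclass
class OrientationAngles:
    """Five angles (degrees) plus a distance (nm) for one interface."""

    hc1: float    # bend: domain-A axis1 vs inter-origin axis
    hc2: float    # bend: domain-A axis2 vs inter-origin axis
    lc1: float    # bend: domain-B axis1 vs inter-origin axis
    lc2: float    # bend: domain-B axis2 vs inter-origin axis
    hl: float     # torsion about the inter-origin axis, (-180, 180]
    distance: float
    interface: str = "Fv"       # 'Fv' or 'CH1CL'

    def as_dict(self) -> dict:
        return {"hc1": self.hc1, "hc2": self.hc2, "lc1": self.lc1,
                "lc2": self.lc2, "hl": self.hl, "distance": self.distance}


def _angle_deg(u, v):
    c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def interdomain_orientation(frame_a: DomainFrame, frame_b: DomainFrame,
                            interface: str = "Fv") -> OrientationAngles:
    """Bend/torsion angles and distance between two domain frames.

    The torsion is the signed angle between the projections of the two
    primary axes onto the plane perpendicular to the inter-origin axis
    (falling back to the secondary axes if a primary axis is parallel to
    it); bends measure each domain's axis 1/2 against the inter-origin axis
    (pointing away from the respective domain).
    """
    c = frame_b.origin - frame_a.origin
    dist = float(np.linalg.norm(c))
    if dist < 1e-12:
        raise ValueError("coincident domain origins")
    ch = c / dist

    def torsion_ref(frame):
        for ax in (frame.axes[0], frame.axes[1]):
            proj = ax - (ax @ ch) * ch
            if np.linalg.norm(proj) > 1e-8:
                return proj / np.linalg.norm(proj)
        raise ValueError("both axes parallel to the inter-origin axis")

    pa, pb = torsion_ref(frame_a), torsion_ref(frame_b)
    hl = float(np.degrees(np.arctan2(np.cross(pa, pb) @ ch, pa @ pb)))
    return OrientationAngles(
        hc1=_angle_deg(frame_a.axes[0], ch), hc2=_angle_deg(frame_a.axes[1], ch),
        lc1=_angle_deg(frame_b.axes[0], -ch), lc2=_angle_deg(frame_b.axes[1], -ch),
        hl=hl, distance=dist, interface=interface)


def orientation_series(traj, domain_a: str, domain_b: str,
                       interface: str = "Fv") -> pd.DataFrame:
    """Per-frame orientation angles between two domains of a trajectory."""
    top = traj.topology
    sa, sb = top.select(domain=domain_a), top.select(domain=domain_b)
    rows = []
    for f in range(traj.n_frames):
        fa = domain_frame(traj.coords[f][sa])
        fb = domain_frame(traj.coords[f][sb])
        ang = interdomain_orientation(fa, fb, interface=interface)
        rows.append({"frame": f, **ang.as_dict()})
    return pd.DataFrame(rows)


def _circular_mean_deg(a):
    rad = np.radians(a)
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def _circular_std_deg(a):
    rad = np.radians(a)
    r = np.hypot(np.mean(np.sin(rad)), np.mean(np.cos(rad)))
    r = min(max(r, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def orientation_shift(series: pd.DataFrame, report: TransitionReport | None = None,
                      window_frames: int = 10) -> pd.DataFrame:
    """Angle shifts and standard deviations up to the end of dissociation.

    The analysed span runs from the start through the encounter -> unbound
    frame (series end if absent); the shift of each angle is the absolute
    difference between its mean over the last and the first ``window_frames``
    frames of the span, the SD is taken over the whole span.  The torsion
    uses circular statistics.  The max-shift angle is flagged.
    """
    if len(series) == 0:
        raise ValueError("empty orientation series")
    end = len(series)
    if report is not None and report.encounter_unbound is not None:
        frames = series["frame"].to_numpy()
        end = int(np.searchsorted(frames, report.encounter_unbound[0])) + 1
        end = min(max(end, 2), len(series))
    span = series.iloc[:end]
    w = min(window_frames, max(1, len(span) // 2))
    rows = []
    for col in ("hc1", "hc2", "lc1", "lc2", "hl"):
        vals = span[col].to_numpy(dtype=float)
        if col == "hl":
            shift = abs(_circular_mean_deg(vals[-w:]) - _circular_mean_deg(vals[:w]))
            shift = min(shift, 360.0 - shift)
            sd = _circular_std_deg(vals)
        else:
            shift = abs(float(np.mean(vals[-w:]) - np.mean(vals[:w])))
            sd = float(np.std(vals))
        rows.append({"angle": col, "shift_deg": shift, "sd_deg": sd})
    df = pd.DataFrame(rows)
    df["max_shift"] = df["shift_deg"] == df["shift_deg"].max()
    return df
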