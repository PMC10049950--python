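"""Per-frame structural descriptors and typed inter-domain contact detection.

The dissociation coordinate is described by four per-frame quantities:

* ``cv``   — inter-chain COM distance (the biased collective variable),
* ``q``    — fraction of native inter-chain contacts of the starting frame,
* ``d1``   — VH-VL COM distance, ``d2`` — CH1-CL COM distance,
* ``sasa`` — solvent-accessible surface area (Shrake-Rupley).

Contacts between inter-chain residue pairs are typed geometrically on bead
chemistry labels: hydrogen bonds (backbone/backbone, side-chain/backbone,
side-chain/side-chain, distinguished by a direction-vector surrogate for the
donor-H alignment since beads carry no hydrogens), salt bridges between
opposite formal charges, and hydrophobic pairs.  There is deliberately no
generic van-der-Waals category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import BeadStructure, BeadTrajectory

__all__ = [
    "NativeContactSet", "ContactCriteria", "ContactEvents", "DescriptorTrace",
    "native_contact_set", "fraction_native_contacts", "com_distance", "sasa",
    "detect_contacts", "detect_contacts_trajectory", "compute_trace",
]

TRACE_COLUMNS = ["frame", "time_ps", "cv_nm", "q", "d1_nm", "d2_nm", "sasa_nm2"]


def validate_trace(df: pd.DataFrame) -> pd.DataFrame:
    """Check descriptor-trace invariants; returns the frame."""
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"descriptor trace missing columns {missing}")
    if ((df["q"] < 0) | (df["q"] > 1)).any():
        raise ValueError("q out of [0, 1]")
    for c in ("cv_nm", "d1_nm", "d2_nm", "sasa_nm2"):
        if (df[c] < 0).any():
            raise ValueError(f"{c} must be non-negative")
    if not df["frame"].is_monotonic_increasing or df["frame"].duplicated().any():
        raise ValueError("frame indices must be strictly increasing")
    return df


# kept as an alias for the container used throughout: a validated DataFrame
DescriptorTrace = pd.DataFrame


# --------------------------------------------------------------------------- #
# Native contacts
# --------------------------------------------------------------------------- #

@dataclass
class NativeContactSet:
    """Reference-frame contact pairs used to evaluate q."""

    reference_frame: int
    cutoff: float                # nm
    pairs: np.ndarray            # (m, 2) int, unordered unique

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def native_contact_set(reference: BeadStructure, cutoff: float = 0.45,
                       interchain_only: bool = True,
                       reference_frame: int = 0) -> NativeContactSet:
    """All (inter-chain) bead pairs within ``cutoff`` in the reference frame."""
    if interchain_only and len(set(reference.chain_id)) < 2:
        raise ValueError("interchain_only requires at least two chains")
    tree = cKDTree(reference.coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if interchain_only and len(pairs):
        keep = reference.chain_id[pairs[:, 0]] != reference.chain_id[pairs[:, 1]]
        pairs = pairs[keep]
    pairs = np.sort(pairs, axis=1)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    if len(pairs) == 0:
        warnings.warn("empty native contact set; q is undefined downstream")
    return NativeContactSet(reference_frame=reference_frame, cutoff=cutoff,
                            pairs=pairs)


def fraction_native_contacts(frame, native: NativeContactSet,
                             tolerance_factor: float = 1.2) -> float:
    """Fraction of native pairs still within ``tolerance_factor * cutoff``."""
    if native.n_pairs == 0:
        raise ValueError("q undefined for an empty native contact set")
    coords = frame.coords if isinstance(frame, BeadStructure) else np.asarray(frame)
    d = np.linalg.norm(coords[native.pairs[:, 0]] - coords[native.pairs[:, 1]],
                       axis=1)
    return float(np.mean(d <= tolerance_factor * native.cutoff))


def com_distance(frame, selection_a, selection_b, masses=None) -> float:
    """Distance between the mass-weighted centroids of two bead selections."""
    if isinstance(frame, BeadStructure):
        coords, masses = frame.coords, frame.masses
    else:
        coords = np.asarray(frame, dtype=float)
        masses = np.ones(len(coords)) if masses is None else np.asarray(masses, float)
    a = np.asarray(selection_a, dtype=int)
    b = np.asarray(selection_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("selections must be nonempty")
    if np.any(masses[a] <= 0) or np.any(masses[b] <= 0):
        raise ValueError("masses must be positive")
    com_a = np.average(coords[a], axis=0, weights=masses[a])
    com_b = np.average(coords[b], axis=0, weights=masses[b])
    return float(np.linalg.norm(com_a - com_b))


# --------------------------------------------------------------------------- #
# SASA
# --------------------------------------------------------------------------- #

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Rotate a bead cloud into a deterministic principal-axis frame.

    Makes the point-sampled surface estimate invariant under rigid motions
    of the input: any rotation/translation maps to the same canonical pose
    (up to float rounding).  Signs follow the first/last bead, the third
    axis closes a right-handed triad.
    """
    cen = coords - coords.mean(axis=0)
    if len(cen) < 3:
        if len(cen) == 2:
            v = cen[1] - cen[0]
            n = np.linalg.norm(v)
            if n > 0:
                # align the pair axis with z
                z = v / n
                x = np.array([1.0, 0.0, 0.0])
                if abs(z @ x) > 0.9:
                    x = np.array([0.0, 1.0, 0.0])
                x = x - (x @ z) * z
                x /= np.linalg.norm(x)
                rot = np.vstack([x, np.cross(z, x), z])
                return cen @ rot.T
        return cen
    cov = cen.T @ cen
    _, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1].T          # rows, decreasing variance
    for i, ref in enumerate((0, -1)):
        if axes[i] @ cen[ref] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return cen @ axes.T


def sasa(frame, radii=None, probe: float = 0.14, n_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area in nm^2.

    Each bead is dressed with ``n_points`` test points on its solvent-extended
    sphere (radius + probe); a point counts as accessible if it lies outside
    every neighbour's extended sphere.  Coordinates are brought into a
    canonical principal-axis pose first, so the estimate is invariant under
    rigid-body motion of the frame.
    """
    if isinstance(frame, BeadStructure):
        coords = frame.coords
        if radii is None:
            radii = np.full(frame.n_beads, frame.radius)
    else:
        coords = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float) if np.ndim(radii) else \
        np.full(len(coords), float(radii))
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    if n_points < 96:
        raise ValueError("n_points must be >= 96")
    coords = _canonical_orientation(coords)
    ext = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    area = 0.0
    rmax = ext.max()
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + rmax)
                 if j != i]
        if neigh:
            d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (ext[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area += 4.0 * np.pi * ext[i] ** 2 * frac
    return float(area)


# --------------------------------------------------------------------------- #
# Typed contacts
# --------------------------------------------------------------------------- #

CONTACT_TYPES = ("hbond_bb_bb", "hbond_sc_bb", "hbond_sc_sc",
                 "salt_bridge", "hydrophobic")

_DONOR_CLASSES = {"donor", "donor_acceptor", "pos"}
_ACCEPTOR_CLASSES = {"acceptor", "donor_acceptor", "neg"}
_CHARGE = {"pos": 1, "neg": -1}


@dataclass
class ContactCriteria:
    """Geometric thresholds for bead-level contact typing (nm / degrees)."""

    hbond_dist: float = 0.35
    hbond_angle: float = 110.0   # donor->acceptor vs donor->bonded-neighbour
    salt_dist: float = 0.40
    phobic_dist: float = 0.45


@dataclass
class ContactEvents:
    """Typed inter-chain residue-pair contacts with per-frame presence bits."""

    meta: pd.DataFrame           # chainA,resA,groupA,chainB,resB,groupB,type
    present: np.ndarray          # (n_events, n_frames) bool

    @property
    def n_events(self) -> int:
        return len(self.meta)

    @property
    def n_frames(self) -> int:
        return self.present.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per (frame, event)."""
        rows = []
        for f in range(self.n_frames):
            df = self.meta.copy()
            df.insert(0, "frame", f)
            df["present"] = self.present[:, f]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _bonded_neighbour(structure: BeadStructure) -> np.ndarray:
    """Index of each bead's chain neighbour (previous residue, else next)."""
    n = structure.n_beads
    neigh = np.full(n, -1, dtype=int)
    for c in set(structure.chain_id):
        sel = np.flatnonzero(structure.chain_id == c)
        order = sel[np.argsort(structure.res_id[sel])]
        for k, i in enumerate(order):
            neigh[i] = order[k - 1] if k > 0 else (order[k + 1] if len(order) > 1 else i)
    return neigh


def _candidate_pairs(structure: BeadStructure, max_dist: float) -> np.ndarray:
    tree = cKDTree(structure.coords)
    pairs = tree.query_pairs(max_dist, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    keep = structure.chain_id[pairs[:, 0]] != structure.chain_id[pairs[:, 1]]
    return pairs[keep]


def _classify_pair(structure, criteria, neigh, i, j, dist):
    """All contact types carried by one inter-chain bead pair at distance dist."""
    ci, cj = structure.bead_class[i], structure.bead_class[j]
    types = []
    if ci == "phobic" and cj == "phobic" and dist <= criteria.phobic_dist:
        types.append("hydrophobic")
    qi, qj = _CHARGE.get(ci, 0), _CHARGE.get(cj, 0)
    if qi * qj < 0 and dist <= criteria.salt_dist:
        types.append("salt_bridge")
    if dist <= criteria.hbond_dist:
        for d, a in ((i, j), (j, i)):
            if structure.bead_class[d] in _DONOR_CLASSES and \
                    structure.bead_class[a] in _ACCEPTOR_CLASSES:
                nd = neigh[d]
                v_da = structure.coords[a] - structure.coords[d]
                v_dn = structure.coords[nd] - structure.coords[d]
                denom = np.linalg.norm(v_da) * np.linalg.norm(v_dn)
                if denom == 0:
                    continue
                ang = np.degrees(np.arccos(np.clip(v_da @ v_dn / denom, -1, 1)))
                if ang >= criteria.hbond_angle:
                    mo = sorted((structure.moiety[d], structure.moiety[a]))
                    hb = {("bb", "bb"): "hbond_bb_bb",
                          ("bb", "sc"): "hbond_sc_bb",
                          ("sc", "sc"): "hbond_sc_sc"}[tuple(mo)]
                    if hb not in types:
                        types.append(hb)
                    break
    return types


def detect_contacts(structure: BeadStructure,
                    criteria: ContactCriteria | None = None) -> pd.DataFrame:
    """Typed inter-chain contacts in one frame.

    Returns a DataFrame (chainA,resA,groupA,chainB,resB,groupB,type); a pair
    may carry several types.  Beads with an unknown chemistry class are
    rejected by the structure container itself.
    """
    criteria = criteria or ContactCriteria()
    neigh = _bonded_neighbour(structure)
    maxd = max(criteria.hbond_dist, criteria.salt_dist, criteria.phobic_dist)
    rows = []
    for i, j in _candidate_pairs(structure, maxd):
        if structure.chain_id[i] == "L":      # report H-chain residue first
            i, j = j, i
        dist = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
        for t in _classify_pair(structure, criteria, neigh, i, j, dist):
            rows.append((structure.chain_id[i], int(structure.res_id[i]),
                         structure.group[i], structure.chain_id[j],
                         int(structure.res_id[j]), structure.group[j], t))
    df = pd.DataFrame(rows, columns=["chainA", "resA", "groupA",
                                     "chainB", "resB", "groupB", "type"])
    return df.sort_values(["resA", "resB", "type"]).reset_index(drop=True)


def detect_contacts_trajectory(traj: BeadTrajectory,
                               criteria: ContactCriteria | None = None
                               ) -> ContactEvents:
    """Contacts over all frames as presence bits on the union of events."""
    criteria = criteria or ContactCriteria()
    per_frame = [detect_contacts(traj.frame(f), criteria)
                 for f in range(traj.n_frames)]
    keys = {}
    for df in per_frame:
        for row in df.itertuples(index=False):
            keys.setdefault(tuple(row), len(keys))
    meta = pd.DataFrame(list(keys), columns=["chainA", "resA", "groupA",
                                             "chainB", "resB", "groupB", "type"])
    present = np.zeros((len(keys), traj.n_frames), dtype=bool)
    for f, df in enumerate(per_frame):
        for row in df.itertuples(index=False):
            present[keys[tuple(row)], f] = True
    return ContactEvents(meta=meta, present=present)


# --------------------------------------------------------------------------- #
# Full trace
# --------------------------------------------------------------------------- #

def compute_trace(traj: BeadTrajectory, native: NativeContactSet | None = None,
                  tolerance_factor: float = 1.2, native_cutoff: float = 0.45,
                  sasa_n_points: int = 240) -> pd.DataFrame:
    """Descriptor trace (cv, q, d1, d2, sasa) along a bead trajectory.

    The native set defaults to the inter-chain contacts of frame 0.
    """
    top = traj.topology
    if native is None:
        native = native_contact_set(top.with_coords(traj.coords[0]),
                                    cutoff=native_cutoff)
    h, l = top.select(chain="H"), top.select(chain="L")
    vh, vl = top.select(domain="VH"), top.select(domain="VL")
    ch1, cl = top.select(domain="CH1"), top.select(domain="CL")
    rows = []
    for f in range(traj.n_frames):
        frame = top.with_coords(traj.coords[f])
        rows.append({
            "frame": f, "time_ps": f * traj.dt_ps,
            "cv_nm": com_distance(frame, h, l),
            "q": fraction_native_contacts(frame, native, tolerance_factor),
            "d1_nm": com_distance(frame, vh, vl),
            "d2_nm": com_distance(frame, ch1, cl),
            "sasa_nm2": sasa(frame, n_points=sasa_n_points),
        })
    return validate_trace(pd.DataFrame(rows))
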