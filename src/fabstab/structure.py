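"""Bead-model structures and trajectories with chain/domain/group annotations.

A Fab surrogate is a cloud of beads, one bead per residue, split over two
chains (H = VH + CH1, L = VL + CL).  Each bead carries

* a domain label (``VH``, ``VL``, ``CH1``, ``CL``),
* a group label (loop / beta-strand name, e.g. ``h_HI`` or ``CDR-L3``),
* a chemistry class used for contact typing
  (``donor``, ``acceptor``, ``donor_acceptor``, ``pos``, ``neg``,
  ``phobic``, ``none``),
* a moiety flag (``bb`` backbone-like / ``sc`` side-chain-like).

Coordinates are stored in nm.  Structures round-trip through standard PDB
(beads written as CA atoms, coordinates converted to/from Angstrom) with the
annotations in a sidecar JSON file, so externally produced bead models can be
fed into the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .constants import A_TO_NM

DOMAINS = ("VH", "VL", "CH1", "CL")
CHAIN_OF_DOMAIN = {"VH": "H", "CH1": "H", "VL": "L", "CL": "L"}
BEAD_CLASSES = ("donor", "acceptor", "donor_acceptor", "pos", "neg", "phobic", "none")


@dataclass
class BeadStructure:
    """One frame of an annotated bead model (coordinates in nm)."""

    coords: np.ndarray            # (n, 3) float, nm
    chain_id: np.ndarray          # (n,) str, 'H' or 'L'
    res_id: np.ndarray            # (n,) int, unique within a chain
    domain: np.ndarray            # (n,) str in DOMAINS
    group: np.ndarray             # (n,) str
    bead_class: np.ndarray        # (n,) str in BEAD_CLASSES
    moiety: np.ndarray            # (n,) str, 'bb' or 'sc'
    masses: np.ndarray = None     # (n,) float; unit masses by default
    radius: float = 0.3           # nm, single bead radius

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        n = len(self.coords)
        for name in ("chain_id", "res_id", "domain", "group", "bead_class", "moiety"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        if self.masses is None:
            self.masses = np.ones(n)
        self.masses = np.asarray(self.masses, dtype=float)
        unknown = set(self.bead_class) - set(BEAD_CLASSES)
        if unknown:
            raise ValueError(f"unknown bead class(es): {sorted(unknown)}")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def select(self, *, chain: str | None = None, domain: str | None = None) -> np.ndarray:
        """Indices of beads matching a chain and/or domain label."""
        mask = np.ones(self.n_beads, dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if domain is not None:
            mask &= self.domain == domain
        return np.flatnonzero(mask)

    def with_coords(self, coords: np.ndarray) -> "BeadStructure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    # ------------------------------------------------------------------ PDB I/O

    def _atom_array(self, coords_nm: np.ndarray) -> struc.AtomArray:
        n = self.n_beads
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(coords_nm, dtype=np.float32) / A_TO_NM
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.res_id.astype(int)
        arr.res_name = np.full(n, "BEA", dtype="U5")
        arr.atom_name = np.full(n, "CA", dtype="U6")
        arr.element = np.full(n, "C", dtype="U2")
        arr.hetero = np.zeros(n, dtype=bool)
        return arr

    def _annotation_dict(self) -> dict:
        ann = {}
        for i in range(self.n_beads):
            key = f"{self.chain_id[i]}:{int(self.res_id[i])}"
            ann[key] = {
                "domain": str(self.domain[i]),
                "group": str(self.group[i]),
                "class": str(self.bead_class[i]),
                "moiety": str(self.moiety[i]),
            }
        return {"radius_nm": self.radius, "beads": ann}

    def to_pdb(self, path: str | Path, annotation_path: str | Path | None = None) -> None:
        """Write as a single-MODEL PDB plus a sidecar annotation JSON."""
        path = Path(path)
        f = pdb.PDBFile()
        pdb.set_structure(f, self._atom_array(self.coords))
        f.write(str(path))
        ann_path = Path(annotation_path) if annotation_path else path.with_suffix(".annotations.json")
        ann_path.write_text(json.dumps(self._annotation_dict(), indent=1))

    @classmethod
    def from_pdb(cls, path: str | Path, annotation_path: str | Path | None = None,
                 radius: float = 0.3) -> "BeadStructure":
        path = Path(path)
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        ann_path = Path(annotation_path) if annotation_path else path.with_suffix(".annotations.json")
        return cls._from_atoms(arr, ann_path, radius)

    @classmethod
    def _from_atoms(cls, arr, ann_path: Path, radius: float) -> "BeadStructure":
        ann = json.loads(Path(ann_path).read_text()) if Path(ann_path).exists() else None
        n = arr.array_length()
        chain = arr.chain_id.astype("U1")
        res = arr.res_id.astype(int)
        domain = np.full(n, "VH", dtype="U4")
        group = np.full(n, "none", dtype="U16")
        bclass = np.full(n, "none", dtype="U16")
        moiety = np.full(n, "bb", dtype="U2")
        if ann is not None:
            radius = float(ann.get("radius_nm", radius))
            beads = ann["beads"]
            for i in range(n):
                rec = beads.get(f"{chain[i]}:{res[i]}")
                if rec is not None:
                    domain[i] = rec["domain"]
                    group[i] = rec["group"]
                    bclass[i] = rec["class"]
                    moiety[i] = rec["moiety"]
        return cls(
            coords=arr.coord.astype(float) * A_TO_NM,
            chain_id=chain, res_id=res, domain=domain, group=group,
            bead_class=bclass, moiety=moiety, radius=radius,
        )


@dataclass
class BeadTrajectory:
    """Multi-frame coordinates sharing one :class:`BeadStructure` topology."""

    topology: BeadStructure
    coords: np.ndarray            # (n_frames, n, 3), nm
    dt_ps: float = 1.0            # frame spacing

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_beads, 3):
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame(self, i: int) -> BeadStructure:
        return self.topology.with_coords(self.coords[i])

    def to_pdb(self, path: str | Path, annotation_path: str | Path | None = None) -> None:
        """Write as a multi-MODEL PDB plus sidecar annotations."""
        path = Path(path)
        top = self.topology
        stack = struc.stack([top._atom_array(self.coords[i]) for i in range(self.n_frames)])
        f = pdb.PDBFile()
        pdb.set_structure(f, stack)
        f.write(str(path))
        ann_path = Path(annotation_path) if annotation_path else path.with_suffix(".annotations.json")
        ann_path.write_text(json.dumps(top._annotation_dict(), indent=1))

    @classmethod
    def from_pdb(cls, path: str | Path, annotation_path: str | Path | None = None,
                 dt_ps: float = 1.0, radius: float = 0.3) -> "BeadTrajectory":
        path = Path(path)
        stack = pdb.PDBFile.read(str(path)).get_structure()
        ann_path = Path(annotation_path) if annotation_path else path.with_suffix(".annotations.json")
        top = BeadStructure._from_atoms(stack[0], ann_path, radius)
        return cls(topology=top, coords=stack.coord.astype(float) * A_TO_NM, dt_ps=dt_ps)
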