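"""Structures, trajectories, selections and superposition.

The in-memory containers are deliberately small: a :class:`Structure` is a
flat table of atoms (residue id, atom name, element, mass, coordinates in Å)
and a :class:`Trajectory` is an ordered stack of coordinate frames congruent
with one topology.  PDB serialization is delegated to biotite; the flat
trajectory table (TSV) is the plain-text interchange surface for frames.

Residue numbering is author numbering (the 5HT2A receptor models span
residues 70–399), 1-based, never renumbered on read.  Insertion codes and
alternate locations are rejected with a clear error rather than silently
normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    EmptySelectionError,
    InvalidParameterError,
    ParseError,
    ShapeMismatchError,
)

__all__ = [
    "Structure",
    "Trajectory",
    "Selection",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "kabsch_superpose",
    "apply_transform",
]

#: Atomic masses (amu) used when a file does not carry masses.
ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: Canonical intra-residue atom ordering used by selection resolution.
_CANONICAL_ATOM_ORDER = {"N": 0, "CA": 1, "C": 2, "O": 3}


def _atom_sort_key(name: str) -> tuple:
    return (_CANONICAL_ATOM_ORDER.get(name, 4), name)


@dataclass
class Structure:
    """One conformation of a labelled polymer.

    Parameters
    ----------
    residue_ids : (n,) int array — author residue numbering.
    atom_names : (n,) str array — PDB atom names (``CA``, ``N``, ...).
    elements : (n,) str array.
    masses : (n,) float array, amu.
    coords : (n, 3) float array, Å.
    chain_id : single chain label.
    """

    residue_ids: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_ids)
        if self.coords.shape != (n, 3):
            raise ShapeMismatchError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if len(self.atom_names) != n or len(self.masses) != n or len(self.elements) != n:
            raise ShapeMismatchError("atom annotation arrays disagree in length")
        keys = list(zip(self.residue_ids.tolist(), self.atom_names.tolist()))
        if len(set(keys)) != n:
            raise InvalidParameterError("duplicate (residue_id, atom_name) entries")

    @property
    def n_atoms(self) -> int:
        return len(self.residue_ids)

    def atom_index(self, residue_id: int, atom_name: str = "CA") -> int:
        """Index of one atom; raises ``MissingAtomError`` via KeyError path."""
        hits = np.flatnonzero(
            (self.residue_ids == residue_id) & (self.atom_names == atom_name)
        )
        if hits.size == 0:
            from .errors import MissingAtomError

            raise MissingAtomError(
                f"residue {residue_id} has no atom {atom_name!r}"
            )
        return int(hits[0])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Trajectory:
    """Ordered frames of a Structure with a time axis in ns."""

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    times: np.ndarray  # (n_frames,), ns, strictly increasing

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeMismatchError("trajectory coords must be (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ShapeMismatchError(
                f"frames carry {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ShapeMismatchError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def __getitem__(self, idx) -> "Trajectory":
        """Frame subsetting (slice or index array) preserving the time axis."""
        if isinstance(idx, int):
            idx = [idx]
        return Trajectory(self.topology, self.coords[idx], self.times[idx])


@dataclass(frozen=True)
class Selection:
    """Atom selection: a mode filter, then include/exclude residue filters.

    ``include_residues=None`` means all residues; exclusions are applied
    after the mode filter.  For ``custom`` mode, ``atom_names`` lists the
    names kept per residue.
    """

    mode: str = "ca"
    include_residues: frozenset | None = None
    exclude_residues: frozenset = field(default_factory=frozenset)
    atom_names: tuple = ()

    def __post_init__(self):
        if self.mode not in ("ca", "backbone", "custom"):
            raise InvalidParameterError(f"unknown selection mode {self.mode!r}")
        if self.include_residues is not None:
            object.__setattr__(
                self, "include_residues", frozenset(self.include_residues)
            )
        object.__setattr__(self, "exclude_residues", frozenset(self.exclude_residues))
        if (
            self.include_residues is not None
            and self.include_residues & self.exclude_residues
        ):
            raise InvalidParameterError(
                "include_residues and exclude_residues overlap"
            )


def resolve_selection(structure: Structure, selection: Selection) -> np.ndarray:
    """Resolve a Selection to an ordered atom-index array.

    Order is ascending residue id, then canonical atom-name order
    (N, CA, C, O, then alphabetical).  Pure function of its arguments.
    """
    if selection.mode == "ca":
        keep_names = {"CA"}
    elif selection.mode == "backbone":
        keep_names = {"N", "CA", "C", "O"}
    else:
        keep_names = set(selection.atom_names)
        if not keep_names:
            raise InvalidParameterError("custom selection needs atom_names")

    idx = []
    for i in range(structure.n_atoms):
        rid = int(structure.residue_ids[i])
        name = structure.atom_names[i]
        if name not in keep_names:
            continue
        if selection.include_residues is not None and rid not in selection.include_residues:
            continue
        if rid in selection.exclude_residues:
            continue
        idx.append(i)
    if not idx:
        raise EmptySelectionError("selection resolved to zero atoms")
    idx.sort(
        key=lambda i: (int(structure.residue_ids[i]), _atom_sort_key(structure.atom_names[i]))
    )
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to
    ``reference``.  The rotation is always proper (det +1); the reflection
    branch of the SVD is corrected by flipping the smallest singular axis.

    Raises ``DegenerateInputError`` for fewer than 3 points or (near-)
    collinear reference geometry, where the rotation is not determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ShapeMismatchError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError("need at least 3 points for superposition")
    if weights is None:
        weights = np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise InvalidParameterError("weights must be non-negative with positive sum")

    wsum = w.sum()
    mc = (w[:, None] * mobile).sum(0) / wsum
    rc = (w[:, None] * reference).sum(0) / wsum
    m0 = mobile - mc
    r0 = reference - rc

    # collinearity check on the reference point cloud
    sv = np.linalg.svd(np.sqrt(w)[:, None] * r0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateInputError("reference geometry is (near-)collinear")

    h = (w[:, None] * m0).T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = rc - rot @ mc

    aligned = m0 @ rot.T
    msd = float((w * ((aligned - r0) ** 2).sum(1)).sum() / wsum)
    return rot, trans, float(np.sqrt(max(msd, 0.0)))


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ rotation.T + translation


# ---------------------------------------------------------------------------
# PDB io (via biotite)
# ---------------------------------------------------------------------------

def _prescan_pdb(path) -> int:
    """Validate ATOM/HETATM records, returning their count.

    Rejects insertion codes and alternate locations (never produced by the
    synthetic writers; silently dropping them would corrupt congruence) and
    reports malformed records with their line number.
    """
    n_atom_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            n_atom_lines += 1
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: truncated ATOM record at line {lineno}")
            if line[16] not in (" ",):
                raise ParseError(
                    f"{path}: alternate location indicator at line {lineno}; "
                    "altlocs are not supported"
                )
            if line[26] not in (" ",):
                raise ParseError(
                    f"{path}: insertion code at line {lineno}; insertion codes "
                    "are not supported"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ParseError(
                    f"{path}: unparseable coordinates at line {lineno}"
                ) from None
    if n_atom_lines == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return n_atom_lines


def _structure_from_atom_array(arr, chain_id: str | None = None) -> Structure:
    masses = np.array(
        [ELEMENT_MASSES.get(str(e).upper(), 12.011) for e in arr.element]
    )
    cid = chain_id if chain_id is not None else (str(arr.chain_id[0]) if len(arr.chain_id) else "A")
    return Structure(
        residue_ids=np.asarray(arr.res_id, dtype=int),
        atom_names=np.asarray(arr.atom_name, dtype=object),
        elements=np.asarray(arr.element, dtype=object),
        masses=masses,
        coords=np.asarray(arr.coord, dtype=float),
        chain_id=cid,
    )


def _atom_array_from_structure(structure: Structure):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    arr.chain_id = np.full(n, structure.chain_id, dtype="U4")
    arr.res_id = np.asarray(structure.residue_ids, dtype=int)
    arr.res_name = np.full(n, "ALA", dtype="U5")
    arr.atom_name = np.asarray([str(a) for a in structure.atom_names], dtype="U6")
    arr.element = np.asarray([str(e) for e in structure.elements], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def read_structure(path, format: str = "pdb") -> Structure:
    """Read a single-model PDB file into a Structure (coordinates in Å)."""
    if format != "pdb":
        raise InvalidParameterError(f"unsupported structure format {format!r}")
    _prescan_pdb(path)
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various subclasses
        raise ParseError(f"{path}: {exc}") from exc
    return _structure_from_atom_array(arr)


def write_structure(structure: Structure, path, format: str = "pdb") -> None:
    if format != "pdb":
        raise InvalidParameterError(f"unsupported structure format {format!r}")
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_structure(structure))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Trajectory io
# ---------------------------------------------------------------------------

_FLAT_COLUMNS = ["frame", "time_ns", "residue_id", "atom_name", "x", "y", "z"]


def write_trajectory(traj: Trajectory, path, format: str = "flat_table") -> None:
    """Write a trajectory as a flat TSV table or a multi-model PDB."""
    if format == "flat_table":
        n_f, n_a, _ = traj.coords.shape
        top = traj.topology
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_f), n_a),
                "time_ns": np.repeat(traj.times, n_a),
                "residue_id": np.tile(top.residue_ids, n_f),
                "atom_name": np.tile(top.atom_names, n_f),
                "x": traj.coords[:, :, 0].ravel(),
                "y": traj.coords[:, :, 1].ravel(),
                "z": traj.coords[:, :, 2].ravel(),
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "multi_model_pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arr = _atom_array_from_structure(traj.topology)
        stack = struc.stack(
            [arr] * traj.n_frames
        )
        stack.coord = np.asarray(traj.coords, dtype=np.float32)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    else:
        raise InvalidParameterError(f"unsupported trajectory format {format!r}")


def _check_frame_congruence(top: Structure, rids, names, frame_no) -> None:
    if len(rids) != top.n_atoms:
        raise ShapeMismatchError(
            f"frame {frame_no}: {len(rids)} atoms, topology has {top.n_atoms}"
        )
    if not (
        np.array_equal(np.asarray(rids, dtype=int), top.residue_ids)
        and list(names) == list(top.atom_names)
    ):
        raise ShapeMismatchError(
            f"frame {frame_no}: atom identities do not match topology"
        )


def read_trajectory(path, topology: Structure, format: str = "flat_table") -> Trajectory:
    """Read a trajectory; frames must be congruent with ``topology``.

    The flat table supplies times; a multi-model PDB uses the frame index
    as the time in ns.
    """
    if format == "flat_table":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        missing = [c for c in _FLAT_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        frames, times = [], []
        for frame_no, grp in df.groupby("frame", sort=True):
            if len(grp) != topology.n_atoms:
                raise ParseError(
                    f"{path}: frame {frame_no} has {len(grp)} rows, expected "
                    f"{topology.n_atoms} (truncated file?)"
                )
            _check_frame_congruence(
                topology, grp["residue_id"].to_numpy(), grp["atom_name"].tolist(), frame_no
            )
            frames.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
            times.append(float(grp["time_ns"].iloc[0]))
        if not frames:
            raise ParseError(f"{path}: no frames found")
        return Trajectory(topology, np.stack(frames), np.asarray(times))

    if format == "multi_model_pdb":
        _prescan_pdb(path)
        from biotite.structure.io.pdb import PDBFile

        try:
            pdb = PDBFile.read(str(path))
            stack = pdb.get_structure()
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:  # single model
            coords = coords[None]
        for f in range(coords.shape[0]):
            _check_frame_congruence(
                topology, np.asarray(stack.res_id, dtype=int), list(stack.atom_name), f
            )
        times = np.arange(coords.shape[0], dtype=float)
        return Trajectory(topology, coords, times)

    raise InvalidParameterError(f"unsupported trajectory format {format!r}")
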