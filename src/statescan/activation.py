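"""Activation-state metrics for receptor trajectories.

Implements the observables used to monitor class A GPCR activation:

* Cα distance time series for the ionic-lock pair (R173/E318) and the
  TM5–TM6 pair (Q262/E318);
* the A100 activation index — a linear combination of five inter-residue
  Cα distances (Å) with fixed per-Å weights and intercept 278.88;
* state classification from the score: the three-state model (inactive
  below 0, intermediate up to 55, active from 55) and the two-state model
  split at 25.  Boundary scores go to the more-active class;
* backbone RMSD time series (mass-weighted, after Kabsch superposition)
  and per-residue RMSF.

Distances enter the A100 index in Å; the printed thresholds are only
meaningful on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientFramesError,
    InvalidParameterError,
)
from .structure_io import (
    Selection,
    Structure,
    Trajectory,
    kabsch_superpose,
    resolve_selection,
)

__all__ = [
    "A100Spec",
    "DEFAULT_A100_SPEC",
    "DistanceSeries",
    "StateSeries",
    "ca_distance_series",
    "a100_score_from_distances",
    "a100_series",
    "classify_state",
    "classify_scores",
    "rmsd_series",
    "rmsf",
    "IONIC_LOCK_PAIR",
    "TM5_TM6_PAIR",
]

#: Ionic-lock Cα pair (R3.50 / E6.30) and the TM5–TM6 cavity-opening pair.
IONIC_LOCK_PAIR = (173, 318)
TM5_TM6_PAIR = (262, 318)


@dataclass(frozen=True)
class A100Spec:
    """The A100 activation index: five Cα distance pairs, per-Å weights,
    and an intercept.  Immutable once constructed."""

    pairs: tuple = ((95, 382), (120, 160), (165, 192), (262, 322), (346, 362))
    coefficients: tuple = (-14.43, -7.62, 9.11, -6.32, -5.22)
    intercept: float = 278.88

    def __post_init__(self):
        if len(self.pairs) != 5 or len(self.coefficients) != 5:
            raise InvalidParameterError("A100 uses exactly five pairs and weights")


DEFAULT_A100_SPEC = A100Spec()

#: Classification thresholds in A100 units.
THREE_STATE_INACTIVE_BELOW = 0.0
THREE_STATE_ACTIVE_FROM = 55.0
TWO_STATE_ACTIVE_FROM = 25.0


@dataclass
class DistanceSeries:
    times: np.ndarray  # ns
    values: np.ndarray  # Å
    pair: tuple
    references: dict | None = None  # optional {"closed": Å, "open": Å}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.times, "distance_A": self.values}
        )


@dataclass
class StateSeries:
    times: np.ndarray
    scores: np.ndarray
    labels_3state: np.ndarray
    labels_2state: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "a100_score": self.scores,
                "label_3state": self.labels_3state,
                "label_2state": self.labels_2state,
            }
        )


def _pair_distances(traj: Trajectory, res_a: int, res_b: int) -> np.ndarray:
    ia = traj.topology.atom_index(res_a, "CA")
    ib = traj.topology.atom_index(res_b, "CA")
    diff = traj.coords[:, ia, :] - traj.coords[:, ib, :]
    return np.linalg.norm(diff, axis=1)


def ca_distance_series(
    traj: Trajectory, res_a: int, res_b: int, references: dict | None = None
) -> DistanceSeries:
    """Per-frame Cα–Cα Euclidean distance in Å.

    No superposition is applied: intramolecular distances are invariant
    under rigid motion.  Raises ``MissingAtomError`` naming the residue if
    either Cα is absent.
    """
    return DistanceSeries(
        times=traj.times.copy(),
        values=_pair_distances(traj, res_a, res_b),
        pair=(res_a, res_b),
        references=references,
    )


def a100_score_from_distances(distances, spec: A100Spec = DEFAULT_A100_SPEC):
    """Affine map from the five pair distances (Å) to the A100 score."""
    d = np.asarray(distances, dtype=float)
    if d.shape[-1] != 5:
        raise InvalidParameterError("expected five distances")
    return d @ np.asarray(spec.coefficients) + spec.intercept


def a100_series(traj: Trajectory, spec: A100Spec = DEFAULT_A100_SPEC) -> StateSeries:
    """A100 score per frame plus three- and two-state labels."""
    dists = np.column_stack([_pair_distances(traj, a, b) for a, b in spec.pairs])
    scores = a100_score_from_distances(dists, spec)
    return StateSeries(
        times=traj.times.copy(),
        scores=scores,
        labels_3state=classify_scores(scores, "three_state"),
        labels_2state=classify_scores(scores, "two_state"),
    )


def classify_state(score: float, model: str = "three_state") -> str:
    """Activation label for one score.

    Three-state: inactive below 0, intermediate in [0, 55), active from 55.
    Two-state: inactive below 25, active from 25.  Boundary scores always
    belong to the more-active class.
    """
    if not np.isfinite(score):
        raise InvalidParameterError(f"score must be finite, got {score}")
    if model == "three_state":
        if score < THREE_STATE_INACTIVE_BELOW:
            return "inactive"
        if score < THREE_STATE_ACTIVE_FROM:
            return "intermediate"
        return "active"
    if model == "two_state":
        return "inactive" if score < TWO_STATE_ACTIVE_FROM else "active"
    raise InvalidParameterError(f"unknown model {model!r}")


def classify_scores(scores, model: str = "three_state") -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise InvalidParameterError("scores must be finite")
    return np.asarray([classify_state(float(s), model) for s in scores], dtype=object)


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: Selection,
    mass_weighted: bool = True,
    superpose: bool = True,
) -> pd.DataFrame:
    """Per-frame RMSD (Å) to a reference over a selection.

    With ``superpose=True`` (default, the usual convention) each frame is
    Kabsch-superposed onto the reference over the selection before the
    weighted RMSD is taken; with ``superpose=False`` coordinates are
    compared as-is.
    """
    idx_t = resolve_selection(traj.topology, selection)
    idx_r = resolve_selection(reference, selection)
    if len(idx_t) != len(idx_r):
        raise InvalidParameterError("selection resolves differently on reference")
    weights = traj.topology.masses[idx_t] if mass_weighted else None
    ref = reference.coords[idx_r]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f, idx_t]
        if superpose:
            _, _, out[f] = kabsch_superpose(mob, ref, weights)
        else:
            w = np.ones(len(idx_t)) if weights is None else weights
            msd = float((w * ((mob - ref) ** 2).sum(1)).sum() / w.sum())
            out[f] = np.sqrt(msd)
    return pd.DataFrame({"time_ns": traj.times, "rmsd_A": out})


def rmsf(traj: Trajectory, selection: Selection, align: bool = True) -> pd.Series:
    """Per-residue RMSF (Å) about the time-mean position.

    With ``align=True`` frames are first superposed (mass-weighted) onto
    the time-averaged structure of the selection (two-pass: align to the
    first frame, average, re-align to that average).  Residues with several
    selected atoms report the RMS over their atoms.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    idx = resolve_selection(traj.topology, selection)
    weights = traj.topology.masses[idx]
    coords = traj.coords[:, idx, :].copy()
    if align:
        ref = coords[0]
        for f in range(traj.n_frames):
            rot, trans, _ = kabsch_superpose(coords[f], ref, weights)
            coords[f] = coords[f] @ rot.T + trans
        mean = coords.mean(axis=0)
        for f in range(traj.n_frames):
            rot, trans, _ = kabsch_superpose(coords[f], mean, weights)
            coords[f] = coords[f] @ rot.T + trans
    mean = coords.mean(axis=0)
    msf = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom
    rids = traj.topology.residue_ids[idx]
    per_res = (
        pd.DataFrame({"residue_id": rids, "msf": msf})
        .groupby("residue_id")["msf"]
        .mean()
        .pow(0.5)
    )
    per_res.name = "rmsf_A"
    return per_res
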