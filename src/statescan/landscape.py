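"""Conformational-landscape extraction.

Mass-weighted PCA of the loop-masked receptor core, 2D projection onto the
first two modes, k-means clustering of the projection (up to four
ensembles), centroid-frame extraction, and RMSD comparison of centroids to
named reference conformations — including a direct readout of the TM6
outward displacement that distinguishes "partially-open" states (~4 Å)
from the fully open transducer-bound state (~8 Å).

PCA contract: frames must be superposed onto a common reference over the
analysis selection beforehand (:func:`superpose_trajectory`); an
unsuperposed input is not detectable from the data alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientFramesError, InvalidParameterError
from .structure_io import (
    Selection,
    Structure,
    Trajectory,
    apply_transform,
    kabsch_superpose,
    resolve_selection,
)

__all__ = [
    "PCAModel",
    "ClusterResult",
    "superpose_trajectory",
    "fit_pca",
    "project",
    "kmeans_cluster",
    "choose_k",
    "compare_to_references",
    "tm6_outward_shift",
]


@dataclass
class PCAModel:
    """Mass-weighted PCA of selected coordinates.

    Eigenvalues are in Å²·amu, descending; eigenvectors are orthonormal
    columns over the mass-weighted coordinate space of the selection.
    """

    mean: np.ndarray  # (3k,) mass-weighted mean
    eigenvalues: np.ndarray  # (3k,), descending, >= 0
    eigenvectors: np.ndarray  # (3k, 3k), columns are modes
    selection: Selection
    mass_weights: np.ndarray  # (k,) amu
    atom_indices: np.ndarray  # (k,) indices into the fitting topology


@dataclass
class ClusterResult:
    projection: np.ndarray  # (frames, 2)
    labels: np.ndarray  # (frames,)
    k: int
    centers: np.ndarray  # (k, 2)
    inertia: float
    centroid_frames: np.ndarray  # (k,) frame index nearest each center
    ref_rmsd: dict | None = None  # per-centroid {reference name: Å}
    nearest_reference: list | None = None


def superpose_trajectory(
    traj: Trajectory, selection: Selection, reference: Structure | None = None
) -> Trajectory:
    """Kabsch-align every frame onto a reference over the selection.

    Default reference is the first frame.  The fitted transform is applied
    to all atoms of each frame.  Mass-weighted over the selection.
    """
    ref_struct = reference if reference is not None else traj.frame(0)
    idx = resolve_selection(traj.topology, selection)
    idx_ref = resolve_selection(ref_struct, selection)
    weights = traj.topology.masses[idx]
    ref = ref_struct.coords[idx_ref]
    coords = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coords[f, idx], ref, weights)
        coords[f] = apply_transform(traj.coords[f], rot, trans)
    return Trajectory(traj.topology, coords, traj.times.copy())


def _weighted_flat(traj: Trajectory, idx: np.ndarray, weights: np.ndarray) -> np.ndarray:
    sq = np.sqrt(np.repeat(weights, 3))
    return traj.coords[:, idx, :].reshape(traj.n_frames, -1) * sq


def fit_pca(traj: Trajectory, selection: Selection) -> PCAModel:
    """Diagonalize the mass-weighted covariance of the selected coordinates.

    Requires >= 2 frames.  The covariance trace equals the eigenvalue sum
    (tested to relative 1e-8); tiny negative eigenvalues from round-off
    are clipped to zero.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("PCA needs at least 2 frames")
    idx = resolve_selection(traj.topology, selection)
    weights = traj.topology.masses[idx]
    x = _weighted_flat(traj, idx, weights)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCAModel(
        mean=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        selection=selection,
        mass_weights=weights,
        atom_indices=idx,
    )


def project(traj: Trajectory, model: PCAModel, n_components: int = 2) -> np.ndarray:
    """Per-frame projection onto the leading modes (Å·amu^½ units)."""
    if n_components > model.eigenvectors.shape[1]:
        raise InvalidParameterError(
            f"requested {n_components} components, model has "
            f"{model.eigenvectors.shape[1]}"
        )
    idx = resolve_selection(traj.topology, model.selection)
    x = _weighted_flat(traj, idx, model.mass_weights)
    return (x - model.mean) @ model.eigenvectors[:, :n_components]


def kmeans_cluster(
    projection: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """k-means (k-means++ seeding, ``n_init`` restarts, best inertia kept).

    ``k`` is capped at 4 ensembles.  The centroid frame of each cluster is
    the frame minimizing the Euclidean distance to the cluster center
    (ties: lowest frame index, numpy argmin convention).
    """
    from sklearn.cluster import KMeans

    projection = np.asarray(projection, dtype=float)
    n = projection.shape[0]
    if not 1 <= k <= min(4, n):
        raise InvalidParameterError(f"k must be in 1..min(4, n_frames), got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6)
    labels = km.fit_predict(projection)
    centroid_frames = np.empty(k, dtype=int)
    for c in range(k):
        d = np.linalg.norm(projection - km.cluster_centers_[c], axis=1)
        d[labels != c] = np.inf
        centroid_frames[c] = int(np.argmin(d))
    return ClusterResult(
        projection=projection,
        labels=labels,
        k=k,
        centers=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
        centroid_frames=centroid_frames,
    )


def choose_k(
    projection: np.ndarray,
    seed: int = 0,
    k_max: int = 4,
    min_silhouette: float = 0.25,
) -> int:
    """Pick k in 1..k_max by silhouette score.

    Silhouette is defined for k >= 2; if the best silhouette over 2..k_max
    falls below ``min_silhouette`` the data are treated as one ensemble.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    projection = np.asarray(projection, dtype=float)
    n = projection.shape[0]
    best_k, best_s = 1, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(
            projection
        )
        if len(set(labels.tolist())) < 2:
            continue
        s = silhouette_score(projection, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k if best_s >= min_silhouette else 1


def compare_to_references(
    centroid: Structure,
    references: dict,
    selection: Selection,
    mass_weighted: bool = True,
) -> tuple[dict, str]:
    """Kabsch-aligned RMSD of a centroid against named reference structures.

    Returns ``(rmsds, nearest)`` where nearest is the argmin; ties keep the
    earlier name in the mapping's order.
    """
    if not references:
        raise InvalidParameterError("empty reference set")
    idx_c = resolve_selection(centroid, selection)
    weights = centroid.masses[idx_c] if mass_weighted else None
    rmsds = {}
    for name, ref in references.items():
        idx_r = resolve_selection(ref, selection)
        if len(idx_r) != len(idx_c) or not np.array_equal(
            centroid.residue_ids[idx_c], ref.residue_ids[idx_r]
        ):
            raise InvalidParameterError(
                f"selection not congruent with reference {name!r}"
            )
        _, _, r = kabsch_superpose(centroid.coords[idx_c], ref.coords[idx_r], weights)
        rmsds[name] = r
    nearest = min(rmsds, key=lambda n: rmsds[n])
    return rmsds, nearest


def tm6_outward_shift(
    centroid: Structure,
    closed_ref: Structure,
    tm6_block: tuple = (315, 346),
) -> float:
    """Mean Cα displacement (Å) of the TM6 block after aligning on the rest.

    The centroid is superposed onto the closed reference over all Cα atoms
    outside the block (mass-weighted); the returned value is the mean
    displacement magnitude of the block's Cα atoms — ~8 Å for the fully
    open reference, ~4 Å for a half-open (partially-open) conformation.
    """
    lo, hi = tm6_block
    block_ids = frozenset(range(lo, hi + 1))
    block_sel = Selection(mode="ca", include_residues=block_ids)
    rest_sel = Selection(mode="ca", exclude_residues=block_ids)
    try:
        idx_block_c = resolve_selection(centroid, block_sel)
        idx_block_r = resolve_selection(closed_ref, block_sel)
    except Exception as exc:
        raise InvalidParameterError(f"empty TM6 block {tm6_block}") from exc
    idx_rest_c = resolve_selection(centroid, rest_sel)
    idx_rest_r = resolve_selection(closed_ref, rest_sel)
    weights = centroid.masses[idx_rest_c]
    rot, trans, _ = kabsch_superpose(
        centroid.coords[idx_rest_c], closed_ref.coords[idx_rest_r], weights
    )
    moved = apply_transform(centroid.coords[idx_block_c], rot, trans)
    disp = np.linalg.norm(moved - closed_ref.coords[idx_block_r], axis=1)
    return float(disp.mean())
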