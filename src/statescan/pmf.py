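"""Umbrella-sampling free-energy estimation.

A from-scratch Weighted Histogram Analysis Method (WHAM) solver combines
harmonically biased sampling windows into one unbiased potential of mean
force (PMF) along a 1D reaction coordinate ξ (nm).  Statistical errors come
from a Bayesian bootstrap over whole windows (flat Dirichlet weights), the
profile is zeroed over a bulk region ("free energy zero when the ligand is
in bulk water"), and binding ΔG / ΔΔG / Boltzmann occupancy ratios are
derived from the zeroed profile.

Units: reaction coordinate nm; force constants accepted in kJ·mol⁻¹·nm⁻²
(GROMACS convention) and converted exactly; free energies kcal·mol⁻¹.

WHAM self-consistency equations, iterated until the window free energies
:math:`F_i` stabilize::

    P(b)  ∝  Σ_i n_i(b)  /  Σ_i N_i exp((F_i − w_i(b)) / RT)
    F_i   =  −RT ln Σ_b P(b) exp(−w_i(b) / RT)

with harmonic biases :math:`w_i(ξ) = ½ k_i (ξ − x_i)²` evaluated at bin
centers.  The PMF is ``−RT ln P`` up to a constant fixed by the zeroing
convention; empty bins are undefined (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConvergenceError, InvalidParameterError
from .units import DEFAULT_TEMPERATURE, R_KCAL, kj_to_kcal, rt_kcal

__all__ = [
    "UmbrellaWindow",
    "UmbrellaDataset",
    "PMFProfile",
    "BindingFreeEnergy",
    "OccupancyRatio",
    "Histograms",
    "build_histograms",
    "wham_solve",
    "bayesian_bootstrap",
    "zero_to_bulk",
    "binding_free_energy",
    "ddg",
    "occupancy_ratio",
    "pmf_rmse",
]


@dataclass
class UmbrellaWindow:
    """One biased-sampling window on the reaction coordinate.

    ``force_const`` is the harmonic restraint stiffness in kJ·mol⁻¹·nm⁻²;
    ``force_const = 0`` denotes an unbiased window.
    """

    center: float  # nm
    force_const: float  # kJ·mol⁻¹·nm⁻²
    samples: np.ndarray  # nm
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_const < 0:
            raise InvalidParameterError("force_const must be >= 0")
        if self.samples.size == 0:
            raise InvalidParameterError("window has no samples")


@dataclass
class UmbrellaDataset:
    windows: list
    coordinate_name: str = "com_distance_nm"
    direction: str = "binding_at_low_xi"

    def __post_init__(self):
        if not self.windows:
            raise InvalidParameterError("dataset has no windows")
        temps = {w.temperature for w in self.windows}
        if len(temps) != 1:
            raise InvalidParameterError("all windows must share one temperature")

    @property
    def temperature(self) -> float:
        return self.windows[0].temperature

    def sorted_windows(self) -> list:
        return sorted(self.windows, key=lambda w: w.center)


@dataclass
class PMFProfile:
    """Free energy vs reaction coordinate with per-bin uncertainty.

    ``free_energy`` is NaN on unoccupied bins; ``stderr`` may be all zero
    (single WHAM solve, or the analytic ground truth).
    """

    bin_centers: np.ndarray  # nm
    free_energy: np.ndarray  # kcal·mol⁻¹
    stderr: np.ndarray  # kcal·mol⁻¹
    zero_region: tuple | None = None

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if not (
            self.bin_centers.shape == self.free_energy.shape == self.stderr.shape
        ):
            raise InvalidParameterError("profile arrays disagree in shape")

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


@dataclass
class BindingFreeEnergy:
    dg: float  # kcal·mol⁻¹, well minimum minus bulk (bulk = 0 by convention)
    sd: float
    site_label: str = "OBP"
    state_label: str = "open"

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidParameterError("sd must be >= 0")


@dataclass
class OccupancyRatio:
    ddg: float  # kcal·mol⁻¹ (ΔΔG_EBP−OBP)
    temperature: float
    ratio: float  # p_OBP / p_EBP
    orders_of_magnitude: int


@dataclass
class Histograms:
    """Shared-binning histograms of all windows plus overlap diagnostics."""

    edges: np.ndarray  # (n_bins + 1,)
    counts: np.ndarray  # (n_windows, n_bins), window order = dataset order
    centers_window: np.ndarray  # (n_windows,) bias centers, nm
    force_consts: np.ndarray  # (n_windows,) kJ·mol⁻¹·nm⁻²
    temperature: float
    overlaps: list = field(default_factory=list)  # per adjacent (sorted) pair

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def build_histograms(
    dataset: UmbrellaDataset,
    n_bins: int = 200,
    range: tuple | None = None,
    clip: bool = False,
) -> Histograms:
    """Bin all windows on one shared uniform grid.

    ``range`` must cover every sample unless ``clip=True`` (out-of-range
    samples are then dropped).  The overlap diagnostic counts, for each
    adjacent pair of windows (sorted by center), the bins occupied by both.
    """
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    all_samples = np.concatenate([w.samples for w in dataset.windows])
    if range is None:
        lo, hi = float(all_samples.min()), float(all_samples.max())
        hi = np.nextafter(hi, np.inf)
    else:
        lo, hi = map(float, range)
        if not hi > lo:
            raise InvalidParameterError("empty histogram range")
        if not clip and (all_samples.min() < lo or all_samples.max() > hi):
            raise InvalidParameterError(
                "samples fall outside the histogram range; pass clip=True "
                "to drop them"
            )
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = np.stack(
        [np.histogram(w.samples, bins=edges)[0].astype(float) for w in dataset.windows]
    )
    order = np.argsort([w.center for w in dataset.windows])
    overlaps = []
    for a, b in zip(order[:-1], order[1:]):
        shared = int(np.sum((counts[a] > 0) & (counts[b] > 0)))
        overlaps.append(
            {
                "window_lo": int(a),
                "window_hi": int(b),
                "shared_bins": shared,
            }
        )
    return Histograms(
        edges=edges,
        counts=counts,
        centers_window=np.array([w.center for w in dataset.windows], dtype=float),
        force_consts=np.array([w.force_const for w in dataset.windows], dtype=float),
        temperature=dataset.temperature,
        overlaps=overlaps,
    )


def _bias_matrix(hist: Histograms) -> np.ndarray:
    """Harmonic bias energies w_i(b) in kcal·mol⁻¹, shape (windows, bins)."""
    k_kcal = kj_to_kcal(hist.force_consts)[:, None]
    dx = hist.bin_centers[None, :] - hist.centers_window[:, None]
    return 0.5 * k_kcal * dx**2


def wham_solve(
    histograms: Histograms,
    temperature: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    f_init: np.ndarray | None = None,
    full_output: bool = False,
):
    """Self-consistent WHAM solve; returns an unzeroed :class:`PMFProfile`.

    ``tol`` is dimensionless: iteration stops when the largest change of any
    window free energy falls below ``tol · RT``.  ``f_init`` warm-starts the
    window free energies (used by the bootstrap).  With ``full_output=True``
    returns ``(profile, window_free_energies, n_iter, residual)``.

    Raises :class:`ConvergenceError` (carrying the last residual) if
    ``max_iter`` is exhausted.
    """
    if temperature is None:
        temperature = histograms.temperature
    rt = rt_kcal(temperature)
    counts = histograms.counts
    c_b = counts.sum(axis=0)
    n_i = counts.sum(axis=1)
    occ = c_b > 0
    if not occ.any():
        raise InvalidParameterError("no occupied bins")

    # exp(-w/RT): underflow to 0 for far bins is harmless
    with np.errstate(under="ignore"):
        a = np.exp(-_bias_matrix(histograms) / rt)

    f = np.zeros(len(n_i)) if f_init is None else np.array(f_init, dtype=float)
    resid = np.inf
    for it in range(1, max_iter + 1):
        with np.errstate(under="ignore", over="ignore"):
            z = n_i * np.exp(f / rt)
            denom = z @ a  # (bins,)
            p = np.where(occ & (denom > 0), c_b / np.where(denom > 0, denom, 1.0), 0.0)
            s = a @ p  # (windows,)
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ConvergenceError("WHAM iteration produced non-finite window sums")
        f_new = -rt * np.log(s)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tol * rt:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {resid:.3e} kcal/mol)",
            residual=resid,
        )

    with np.errstate(divide="ignore"):
        g = np.where(occ, -rt * np.log(np.where(occ, p, 1.0)), np.nan)
    profile = PMFProfile(
        bin_centers=histograms.bin_centers,
        free_energy=g,
        stderr=np.zeros_like(g),
    )
    if full_output:
        return profile, f, it, resid
    return profile


def bayesian_bootstrap(
    dataset: UmbrellaDataset,
    n_boot: int = 250,
    seed: int = 0,
    n_bins: int = 200,
    range: tuple | None = None,
    temperature: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    method: str = "window",
) -> PMFProfile:
    """WHAM profile with Bayesian-bootstrap per-bin standard errors.

    ``method="window"`` (default) draws flat Dirichlet weights over whole
    windows and scales each window's histogram (and effective sample count)
    by its weight — the complete-histogram bootstrap style.  As an option,
    ``method="sample"`` multinomially resamples observations within each
    window.  Replicates are gauge-aligned (mean over occupied bins
    subtracted) before the per-bin standard deviation is taken, since each
    WHAM solution is defined only up to a constant.  Deterministic for a
    fixed seed; ``n_boot=1`` yields identically zero stderr.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if method not in ("window", "sample"):
        raise InvalidParameterError(f"unknown bootstrap method {method!r}")
    hist = build_histograms(dataset, n_bins=n_bins, range=range)
    base, f0, _, _ = wham_solve(
        hist, temperature=temperature, tol=tol, max_iter=max_iter, full_output=True
    )
    occ = base.occupied
    rng = np.random.default_rng(seed)
    n_w = hist.counts.shape[0]
    replicates = np.empty((n_boot, hist.counts.shape[1]))
    for r in np.arange(n_boot):  # `range` name is taken by the bin range
        if method == "window":
            w = rng.dirichlet(np.ones(n_w)) * n_w
            counts_r = hist.counts * w[:, None]
        else:
            counts_r = np.stack(
                [
                    rng.multinomial(int(c.sum()), c / c.sum()).astype(float)
                    for c in hist.counts
                ]
            )
        hist_r = replace(hist, counts=counts_r)
        try:
            prof_r = wham_solve(
                hist_r, temperature=temperature, tol=tol, max_iter=max_iter, f_init=f0
            )
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"bootstrap replicate {r}: {exc}", residual=exc.residual
            ) from exc
        g = prof_r.free_energy.copy()
        both = occ & np.isfinite(g)
        g -= np.nanmean(g[both])
        replicates[r] = g
    if n_boot == 1:
        stderr = np.zeros_like(base.free_energy)
    else:
        with np.errstate(invalid="ignore"):
            stderr = np.nanstd(replicates, axis=0, ddof=1)
        stderr = np.where(occ, stderr, 0.0)
    return PMFProfile(
        bin_centers=base.bin_centers,
        free_energy=base.free_energy,
        stderr=stderr,
    )


def _region_mask(profile: PMFProfile, region: tuple) -> np.ndarray:
    lo, hi = region
    return (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & profile.occupied


def zero_to_bulk(profile: PMFProfile, bulk_region: tuple) -> PMFProfile:
    """Subtract the mean free energy over ``bulk_region`` (idempotent)."""
    mask = _region_mask(profile, bulk_region)
    if not mask.any():
        raise InvalidParameterError(
            f"no occupied bins in bulk region {bulk_region}"
        )
    shift = float(np.mean(profile.free_energy[mask]))
    return PMFProfile(
        bin_centers=profile.bin_centers,
        free_energy=profile.free_energy - shift,
        stderr=profile.stderr,
        zero_region=tuple(bulk_region),
    )


def binding_free_energy(
    profile: PMFProfile,
    site_region: tuple,
    site_label: str = "OBP",
    state_label: str = "open",
) -> BindingFreeEnergy:
    """ΔG of binding: the PMF minimum inside the site region (bulk is 0)."""
    mask = _region_mask(profile, site_region)
    if not mask.any():
        raise InvalidParameterError(f"no occupied bins in site region {site_region}")
    idx = np.flatnonzero(mask)
    j = idx[int(np.argmin(profile.free_energy[idx]))]
    return BindingFreeEnergy(
        dg=float(profile.free_energy[j]),
        sd=float(profile.stderr[j]),
        site_label=site_label,
        state_label=state_label,
    )


def ddg(
    site_ebp: BindingFreeEnergy,
    site_obp: BindingFreeEnergy,
    error_mode: str = "quadrature",
) -> tuple[float, float]:
    """ΔΔG_EBP−OBP = ΔG_EBP − ΔG_OBP, with the propagated error.

    Positive values favor the orthosteric pocket.  ``error_mode`` is
    ``"quadrature"`` (default) or ``"linear_sum"``.
    """
    if site_ebp.state_label != site_obp.state_label:
        raise InvalidParameterError(
            f"cannot mix states {site_ebp.state_label!r} and {site_obp.state_label!r}"
        )
    value = site_ebp.dg - site_obp.dg
    if error_mode == "quadrature":
        sd = math.hypot(site_ebp.sd, site_obp.sd)
    elif error_mode == "linear_sum":
        sd = site_ebp.sd + site_obp.sd
    else:
        raise InvalidParameterError(f"unknown error_mode {error_mode!r}")
    return float(value), float(sd)


def occupancy_ratio(
    ddg_value: float, temperature: float = DEFAULT_TEMPERATURE
) -> OccupancyRatio:
    """Boltzmann occupancy ratio p_OBP/p_EBP = exp(ΔΔG / RT)."""
    if temperature <= 0:
        raise InvalidParameterError("temperature must be > 0")
    if not np.isfinite(ddg_value):
        raise InvalidParameterError("ddg must be finite")
    ratio = math.exp(ddg_value / (R_KCAL * temperature))
    return OccupancyRatio(
        ddg=float(ddg_value),
        temperature=float(temperature),
        ratio=ratio,
        orders_of_magnitude=int(math.floor(math.log10(ratio))),
    )


def pmf_rmse(profile: PMFProfile, reference: PMFProfile) -> float:
    """Gauge-invariant RMSE between two profiles on a common grid.

    Both profiles are shifted to zero mean over the mutually occupied bins
    before comparison (a PMF is defined up to a constant).
    """
    if profile.bin_centers.shape != reference.bin_centers.shape or not np.allclose(
        profile.bin_centers, reference.bin_centers
    ):
        raise InvalidParameterError("profiles are on different grids")
    mask = profile.occupied & reference.occupied
    if not mask.any():
        raise InvalidParameterError("no mutually occupied bins")
    a = profile.free_energy[mask]
    b = reference.free_energy[mask]
    a = a - a.mean()
    b = b - b.mean()
    return float(np.sqrt(np.mean((a - b) ** 2)))
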