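"""Synthetic inputs with the statistical structure the analyses assume.

Three families of generators:

* a **toy receptor** — 330 Cα pseudo-atoms (residues 70–399) arranged as an
  idealized seven-helix bundle plus loop arcs and an eighth intracellular
  helix, with a Ballesteros–Weinstein label map for the residues used by
  the activation metrics.  Only the topology matters (contiguity, a
  distinct TM6 block); no chemical realism is attempted.
* **two-state collapse trajectories** — frames interpolating from an "open"
  reference (TM6 tilted outward) toward a "closed" reference with a linear
  mixing schedule and i.i.d. Gaussian coordinate noise, emulating the rapid
  relaxation of the transducer-free open state.
* **umbrella-window samples** from analytic 1D potentials (harmonic,
  double-well, tabulated) plus harmonic biases, drawn by Metropolis
  random-walk sampling of the biased Boltzmann density — ground truth for
  the WHAM estimator is then available in closed form.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import InvalidParameterError, ShapeMismatchError
from .pmf import PMFProfile, UmbrellaDataset, UmbrellaWindow
from .structure_io import Selection, Structure, Trajectory
from .units import DEFAULT_TEMPERATURE, R_KJ, kj_to_kcal, rt_kcal

__all__ = [
    "ToyReceptor",
    "PotentialSpec",
    "make_toy_receptor",
    "make_reference_pair",
    "generate_two_state_trajectory",
    "mixing_schedule",
    "schedule_labels",
    "generate_umbrella_dataset",
    "analytic_pmf",
    "harmonic_potential",
    "double_well_potential",
    "table_potential",
    "constant_potential",
    "loop_excluded_selection",
    "ICL_RANGES",
    "ECL_RANGES",
    "TM6_RANGE",
    "BW_MAP",
]

FIRST_RESIDUE, LAST_RESIDUE = 70, 399

#: Intracellular / extracellular loop residue ranges (inclusive), excluded
#: from PCA and reference alignment because of their flexibility.
ICL_RANGES = ((102, 108), (179, 189), (263, 314))
ECL_RANGES = ((138, 145), (217, 231), (347, 354))

#: The contiguous residue block displaced between the closed and open
#: reference conformations (transmembrane helix 6).
TM6_RANGE = (315, 346)

#: Ballesteros–Weinstein label → residue id for the residues used by the
#: activation index and the ionic-lock / TM5-TM6 distance metrics.  The
#: index's source lists two residues under 4.42 (one is a typo); residue
#: ids are authoritative, labels are metadata ("4.42b" disambiguates).
BW_MAP: Mapping[str, int] = {
    "1.53": 95,
    "2.50": 120,
    "4.42": 160,
    "3.42": 165,
    "4.42b": 192,
    "5.66": 262,
    "6.34": 322,
    "6.58": 346,
    "7.35": 362,
    "7.55": 382,
    "3.50": 173,
    "6.30": 318,
}

_SEGMENTS = (
    ("TM1", 70, 101, "helix"),
    ("ICL1", 102, 108, "loop_low"),
    ("TM2", 109, 137, "helix"),
    ("ECL1", 138, 145, "loop_high"),
    ("TM3", 146, 178, "helix"),
    ("ICL2", 179, 189, "loop_low"),
    ("TM4", 190, 216, "helix"),
    ("ECL2", 217, 231, "loop_high"),
    ("TM5", 232, 262, "helix"),
    ("ICL3", 263, 314, "loop_low"),
    ("TM6", 315, 346, "helix"),
    ("ECL3", 347, 354, "loop_high"),
    ("TM7", 355, 381, "helix"),
    ("H8", 382, 399, "h8"),
)

_CA_MASS = 12.011  # the toy models Cα pseudo-atoms only


@dataclass
class ToyReceptor:
    """A 330-residue Cα-only receptor model with a BW label map."""

    residue_ids: np.ndarray
    ca_coords: np.ndarray  # (330, 3), Å
    masses: np.ndarray  # amu
    bw_map: dict = field(default_factory=lambda: dict(BW_MAP))

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        expected = np.arange(FIRST_RESIDUE, LAST_RESIDUE + 1)
        if not np.array_equal(self.residue_ids, expected):
            raise InvalidParameterError(
                f"residue ids must exactly cover {FIRST_RESIDUE}..{LAST_RESIDUE}"
            )
        if self.ca_coords.shape != (len(expected), 3):
            raise ShapeMismatchError("ca_coords must be (330, 3)")

    def to_structure(self, chain_id: str = "A") -> Structure:
        n = len(self.residue_ids)
        return Structure(
            residue_ids=self.residue_ids,
            atom_names=np.array(["CA"] * n, dtype=object),
            elements=np.array(["C"] * n, dtype=object),
            masses=self.masses,
            coords=self.ca_coords,
            chain_id=chain_id,
        )


def loop_residue_ids() -> frozenset:
    ids = set()
    for lo, hi in ICL_RANGES + ECL_RANGES:
        ids.update(range(lo, hi + 1))
    return frozenset(ids)


def loop_excluded_selection(mode: str = "ca") -> Selection:
    """Cα (or backbone) selection with all six loop ranges excluded."""
    return Selection(mode=mode, exclude_residues=loop_residue_ids())


def _helix_coords(n_res, axis_xy, z_start, direction, phase0):
    """Ideal α-helix: 1.5 Å rise/residue, 100°/turn, 2.3 Å radius."""
    j = np.arange(n_res)
    phi = phase0 + np.deg2rad(100.0) * j
    x = axis_xy[0] + 2.3 * np.cos(phi)
    y = axis_xy[1] + 2.3 * np.sin(phi)
    z = z_start + direction * 1.5 * j
    return np.column_stack([x, y, z])


def _bezier(p0, p1, p2, n):
    t = (np.arange(1, n + 1) / (n + 1))[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def make_toy_receptor(seed: int) -> ToyReceptor:
    """Deterministic toy receptor; coordinates are non-degenerate.

    Helices sit on a 14 Å circle with alternating up/down direction so that
    intracellular loops connect helix bottoms and extracellular loops helix
    tops; H8 runs roughly parallel to the membrane plane below the bundle.
    A small seeded jitter (0.15 Å) breaks exact symmetry.
    """
    rng = np.random.default_rng(seed)
    bundle_r = 14.0
    coords = {}

    # first pass: helices and H8 (loop endpoints need them)
    helix_no = 0
    seg_coords = {}
    for name, lo, hi, kind in _SEGMENTS:
        n = hi - lo + 1
        if kind == "helix":
            theta = 2 * np.pi * helix_no / 7.0
            axis = (bundle_r * np.cos(theta), bundle_r * np.sin(theta))
            direction = -1.0 if helix_no % 2 == 0 else 1.0
            length = 1.5 * (n - 1)
            z_start = direction * (-length / 2.0)
            seg_coords[name] = _helix_coords(n, axis, z_start, direction, theta)
            helix_no += 1
        elif kind == "h8":
            # straight amphipathic helix below the bundle, tangent direction
            theta = 2 * np.pi * 6 / 7.0
            start = np.array(
                [bundle_r * np.cos(theta), bundle_r * np.sin(theta), -26.0]
            )
            tang = np.array([-np.sin(theta), np.cos(theta), 0.0])
            radial = np.array([np.cos(theta), np.sin(theta), 0.0])
            j = np.arange(n)[:, None]
            phi = np.deg2rad(100.0) * np.arange(n)
            wob = 2.3 * (
                np.cos(phi)[:, None] * radial + np.sin(phi)[:, None] * np.array([0, 0, 1.0])
            )
            seg_coords[name] = start + 1.5 * j * tang + wob

    # second pass: loops as quadratic Bezier arcs between helix endpoints
    names = [s[0] for s in _SEGMENTS]
    for i, (name, lo, hi, kind) in enumerate(_SEGMENTS):
        if kind in ("helix", "h8"):
            continue
        n = hi - lo + 1
        p0 = seg_coords[names[i - 1]][-1]
        p2 = seg_coords[names[i + 1]][0]
        mid = 0.5 * (p0 + p2)
        radial = mid[:2]
        norm = np.linalg.norm(radial)
        radial = radial / norm if norm > 0 else np.array([1.0, 0.0])
        bulge = 4.0 + 0.15 * n
        zdir = -1.0 if kind == "loop_low" else 1.0
        ctrl = mid + np.array(
            [radial[0] * bulge, radial[1] * bulge, zdir * (3.0 + 0.1 * n)]
        )
        seg_coords[name] = _bezier(p0, ctrl, p2, n)

    all_coords = np.concatenate([seg_coords[s[0]] for s in _SEGMENTS])
    all_coords = all_coords + rng.normal(0.0, 0.15, size=all_coords.shape)
    residue_ids = np.arange(FIRST_RESIDUE, LAST_RESIDUE + 1)
    return ToyReceptor(
        residue_ids=residue_ids,
        ca_coords=all_coords,
        masses=np.full(len(residue_ids), _CA_MASS),
    )


def make_reference_pair(
    receptor: ToyReceptor, tm6_shift: float, seed: int = 0
) -> tuple[Structure, Structure]:
    """Closed and open reference conformations differing by a rigid TM6 shift.

    The open state displaces the TM6 block by ``tm6_shift`` Å along the unit
    vector from the Cα of the ionic-lock arginine (residue 173) toward the
    Cα of its glutamate partner (residue 318), so the R173–E318 Cα distance
    grows by exactly ``tm6_shift``.  ``seed`` is accepted for interface
    symmetry with the other generators; the construction is deterministic
    given the receptor.
    """
    if tm6_shift <= 0:
        raise InvalidParameterError("tm6_shift must be > 0")
    closed = receptor.to_structure()
    i173 = closed.atom_index(173)
    i318 = closed.atom_index(318)
    axis = closed.coords[i318] - closed.coords[i173]
    axis = axis / np.linalg.norm(axis)
    lo, hi = TM6_RANGE
    block = (closed.residue_ids >= lo) & (closed.residue_ids <= hi)
    open_coords = closed.coords.copy()
    open_coords[block] += tm6_shift * axis
    return closed, closed.with_coords(open_coords)


def mixing_schedule(n_frames: int, collapse_frame: int) -> np.ndarray:
    """Mixing coefficient λ(t): 1 at frame 0, linearly to 0 at the collapse
    frame, 0 afterwards."""
    if not 0 <= collapse_frame <= n_frames:
        raise InvalidParameterError("need 0 <= collapse_frame <= n_frames")
    t = np.arange(n_frames, dtype=float)
    if collapse_frame == 0:
        return np.zeros(n_frames)
    return np.clip(1.0 - t / collapse_frame, 0.0, 1.0)


def schedule_labels(n_frames: int, collapse_frame: int) -> np.ndarray:
    """Nearest-reference label per frame: "open" while λ > 0.5, else
    "closed" — the partition a distance-based clustering can recover."""
    lam = mixing_schedule(n_frames, collapse_frame)
    return np.where(lam > 0.5, "open", "closed")


def generate_two_state_trajectory(
    closed: Structure,
    open_: Structure,
    n_frames: int,
    collapse_frame: int,
    noise_sd: float,
    seed: int,
    dt_ns: float = 0.1,
) -> Trajectory:
    """Open→closed collapse trajectory with Gaussian coordinate noise.

    Frame t is ``λ(t)·open + (1−λ(t))·closed`` plus i.i.d. N(0, noise_sd²)
    noise per coordinate; λ follows :func:`mixing_schedule`.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if closed.n_atoms != open_.n_atoms or not np.array_equal(
        closed.residue_ids, open_.residue_ids
    ):
        raise ShapeMismatchError("closed and open structures are not congruent")
    lam = mixing_schedule(n_frames, collapse_frame)
    coords = (
        lam[:, None, None] * open_.coords[None]
        + (1.0 - lam)[:, None, None] * closed.coords[None]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sd, size=coords.shape)
    times = np.arange(n_frames, dtype=float) * dt_ns
    return Trajectory(closed, coords, times)


# ---------------------------------------------------------------------------
# Analytic 1D potentials and umbrella sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialSpec:
    """Analytic 1D potential on a closed domain of the reaction coordinate.

    ``kind`` ∈ {harmonic, double_well, piecewise_table}; parameters are in
    kcal·mol⁻¹ and nm.  The evaluation must be finite everywhere on the
    domain (checked at construction on a dense probe grid).
    """

    kind: str
    parameters: tuple  # hashable (key, value) pairs
    domain: tuple  # (lo, hi) nm

    def __post_init__(self):
        if self.kind not in ("harmonic", "double_well", "piecewise_table"):
            raise InvalidParameterError(f"unknown potential kind {self.kind!r}")
        lo, hi = self.domain
        if not hi > lo:
            raise InvalidParameterError("empty potential domain")
        probe = np.linspace(lo, hi, 257)
        if not np.all(np.isfinite(self.evaluate(probe))):
            raise InvalidParameterError("potential not finite on its domain")

    @property
    def params(self) -> dict:
        return dict(self.parameters)

    def evaluate(self, x) -> np.ndarray:
        """U(x) in kcal·mol⁻¹ (vectorized)."""
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.kind == "harmonic":
            return 0.5 * p["k"] * (x - p["x0"]) ** 2 + p.get("offset", 0.0)
        if self.kind == "double_well":
            a, b = p["min1"], p["min2"]
            h = p["barrier"]
            m, w = 0.5 * (a + b), 0.5 * (b - a)
            y = x - m
            u = h * (y**2 - w**2) ** 2 / w**4
            # flat shoulders outside the two minima: the domain maximum
            # equals the barrier and the outer basins model flat bulk
            return np.where((x >= a) & (x <= b), u, 0.0) + p.get("offset", 0.0)
        xs = np.asarray(p["xs"], dtype=float)
        ys = np.asarray(p["ys"], dtype=float)
        return np.interp(x, xs, ys) + p.get("offset", 0.0)


def harmonic_potential(k: float, x0: float, domain: tuple, offset: float = 0.0) -> PotentialSpec:
    """½·k·(x−x0)² with k in kcal·mol⁻¹·nm⁻²."""
    return PotentialSpec(
        "harmonic", (("k", float(k)), ("x0", float(x0)), ("offset", float(offset))), tuple(domain)
    )


def double_well_potential(
    barrier: float, domain: tuple, minima: tuple | None = None, offset: float = 0.0
) -> PotentialSpec:
    """Quartic barrier of height ``barrier`` between two flat basins.

    Default minima sit 20% of the span inside each domain edge.
    """
    lo, hi = domain
    if minima is None:
        span = hi - lo
        minima = (lo + 0.2 * span, hi - 0.2 * span)
    a, b = minima
    if not (lo <= a < b <= hi):
        raise InvalidParameterError("minima must lie ordered inside the domain")
    return PotentialSpec(
        "double_well",
        (
            ("barrier", float(barrier)),
            ("min1", float(a)),
            ("min2", float(b)),
            ("offset", float(offset)),
        ),
        tuple(domain),
    )


def table_potential(xs, ys, offset: float = 0.0) -> PotentialSpec:
    xs = tuple(float(v) for v in xs)
    ys = tuple(float(v) for v in ys)
    if len(xs) != len(ys) or len(xs) < 2:
        raise InvalidParameterError("table needs >= 2 (x, y) pairs")
    if not all(b > a for a, b in zip(xs[:-1], xs[1:])):
        raise InvalidParameterError("table x values must be strictly increasing")
    return PotentialSpec(
        "piecewise_table",
        (("xs", xs), ("ys", ys), ("offset", float(offset))),
        (xs[0], xs[-1]),
    )


def constant_potential(domain: tuple, value: float = 0.0) -> PotentialSpec:
    return table_potential([domain[0], domain[1]], [value, value])


def generate_umbrella_dataset(
    potential: PotentialSpec,
    n_windows: int,
    spacing: float,
    force_const: float,
    n_samples: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    burn_in: int = 1000,
    thinning: int = 10,
) -> UmbrellaDataset:
    """Metropolis samples of the biased Boltzmann density per window.

    Windows are centered symmetrically in the potential's domain with the
    given uniform spacing (nm) and harmonic stiffness (kJ·mol⁻¹·nm⁻²).
    Each chain starts at its window center, adapts its step size toward
    ~40% acceptance during burn-in (then freezes it, preserving detailed
    balance), and keeps every ``thinning``-th state.  Proposals outside the
    domain are rejected, i.e. the density is the Boltzmann density
    truncated to the domain — matching :func:`analytic_pmf` on that domain.
    """
    if n_windows < 1:
        raise InvalidParameterError("n_windows must be >= 1")
    if force_const <= 0:
        raise InvalidParameterError("force_const must be > 0")
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    lo, hi = potential.domain
    span = hi - lo
    width = (n_windows - 1) * spacing
    if width > span:
        raise InvalidParameterError(
            f"domain of width {span} nm too small for {n_windows} windows at "
            f"{spacing} nm spacing"
        )
    start = lo + 0.5 * (span - width)
    centers = start + spacing * np.arange(n_windows)

    rt = rt_kcal(temperature)
    k_kcal = kj_to_kcal(force_const)
    rng = np.random.default_rng(seed)

    def energy(x):
        return potential.evaluate(x) + 0.5 * k_kcal * (x - centers) ** 2

    x = centers.copy()
    e = energy(x)
    # bias-dominated width sets the initial proposal scale
    step = np.full(n_windows, 2.5 * np.sqrt(R_KJ * temperature / force_const))
    accepted = np.zeros(n_windows)
    samples = np.empty((n_windows, n_samples))
    n_steps = burn_in + thinning * n_samples
    collected = 0
    for t in range(n_steps):
        prop = x + step * rng.normal(size=n_windows)
        inside = (prop >= lo) & (prop <= hi)
        e_prop = np.where(inside, energy(np.where(inside, prop, x)), np.inf)
        with np.errstate(over="ignore"):
            accept = rng.random(n_windows) < np.exp(np.minimum((e - e_prop) / rt, 0.0))
        accept &= inside
        x = np.where(accept, prop, x)
        e = np.where(accept, e_prop, e)
        if t < burn_in:
            accepted += accept
            if (t + 1) % 50 == 0:
                rate = accepted / 50.0
                step = np.clip(step * np.exp(rate - 0.4), 1e-4, 1.0)
                accepted[:] = 0.0
        else:
            if (t - burn_in + 1) % thinning == 0:
                samples[:, collected] = x
                collected += 1
    assert collected == n_samples
    windows = [
        UmbrellaWindow(
            center=float(centers[i]),
            force_const=float(force_const),
            samples=samples[i],
            temperature=temperature,
        )
        for i in range(n_windows)
    ]
    return UmbrellaDataset(windows=windows)


def analytic_pmf(
    potential: PotentialSpec, grid: np.ndarray, zero_region: tuple | None = None
) -> PMFProfile:
    """Ground-truth PMF: U evaluated on ``grid``, zeroed and noise-free.

    With ``zero_region`` the mean over that interval is subtracted
    (matching :func:`statescan.pmf.zero_to_bulk`), otherwise the grid
    minimum is the zero.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = potential.domain
    if grid.min() < lo or grid.max() > hi:
        raise InvalidParameterError("grid extends outside the potential domain")
    u = potential.evaluate(grid)
    if zero_region is not None:
        zlo, zhi = zero_region
        mask = (grid >= zlo) & (grid <= zhi)
        if not mask.any():
            raise InvalidParameterError("no grid points in zero_region")
        u = u - u[mask].mean()
    else:
        u = u - u.min()
    return PMFProfile(
        bin_centers=grid,
        free_energy=u,
        stderr=np.zeros_like(u),
        zero_region=tuple(zero_region) if zero_region is not None else None,
    )
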