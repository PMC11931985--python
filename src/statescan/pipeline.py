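"""End-to-end reproducible runs: synthesize → analyze → report.

A run is driven by one nested configuration mapping (YAML on disk) with a
single seed; every stage writes plain-text outputs (CSV/TSV/PDB/JSON) plus
a JSON manifest with a parameter echo and per-file SHA-256 checksums, so a
config + seed reproduces its outputs bit-identically for the deterministic
stages.  Logs go to stderr, data to files only.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import (
    IONIC_LOCK_PAIR,
    TM5_TM6_PAIR,
    a100_series,
    ca_distance_series,
    rmsd_series,
)
from .errors import ConfigurationError
from .landscape import (
    choose_k,
    compare_to_references,
    fit_pca,
    kmeans_cluster,
    project,
    superpose_trajectory,
    tm6_outward_shift,
)
from .pmf import (
    UmbrellaDataset,
    UmbrellaWindow,
    bayesian_bootstrap,
    binding_free_energy,
    build_histograms,
    ddg,
    occupancy_ratio,
    zero_to_bulk,
)
from .structure_io import (
    Selection,
    read_structure,
    read_trajectory,
    write_structure,
    write_trajectory,
)
from .synthetic import (
    TM6_RANGE,
    generate_two_state_trajectory,
    generate_umbrella_dataset,
    loop_excluded_selection,
    make_reference_pair,
    make_toy_receptor,
    table_potential,
)
from .units import DEFAULT_TEMPERATURE

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "make_table1_report"]

log = logging.getLogger("statescan")

STAGES = ("synth", "activation", "landscape", "pmf")

#: A binding-like demo potential along the unbinding coordinate: a deep
#: orthosteric-like well, a shallower extended-pocket-like well, flat bulk.
_DEMO_POTENTIAL_TABLE = {
    "xs": [0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.5, 2.0, 2.5, 4.0],
    "ys": [-6.0, -10.5, -12.2, -10.5, -8.5, -7.5, -7.0, -4.5, -1.2, 0.0, 0.0],
}

DEFAULT_CONFIG = {
    "stage": "all",
    "seed": 7,
    "outdir": "statescan_run",
    "synth": {
        "tm6_shift": 8.0,
        "n_frames": 400,
        "collapse_frame": 100,
        "noise_sd": 0.3,
        "dt_ns": 0.1,
        "umbrella": {
            "potential_table": _DEMO_POTENTIAL_TABLE,
            "n_windows": 40,
            "spacing": 0.1,
            "force_const": 1000.0,  # kJ·mol⁻¹·nm⁻²
            "n_samples": 500,
            "temperature": DEFAULT_TEMPERATURE,
        },
    },
    "activation": {},
    "landscape": {"k": "auto"},
    "pmf": {
        "n_bins": 100,
        "n_boot": 25,
        "bulk_region": [3.6, 4.0],
        "site_regions": {"OBP": [0.0, 0.8], "EBP": [0.8, 1.8]},
        "state_label": "open",
        "temperature": DEFAULT_TEMPERATURE,
    },
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults ← YAML file ← overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        with open(p) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config root must be a mapping: {p}")
        cfg = _deep_update(cfg, loaded)
    if overrides:
        cfg = _deep_update(cfg, overrides)
    if cfg["stage"] not in STAGES + ("all",):
        raise ConfigurationError(f"unknown stage {cfg['stage']!r}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _fmt(x):
    return float(f"{x:.6g}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_synth(cfg: dict, outdir: Path) -> list:
    p = cfg["synth"]
    seed = int(cfg["seed"])
    receptor = make_toy_receptor(seed)
    closed, open_ = make_reference_pair(receptor, float(p["tm6_shift"]))
    traj = generate_two_state_trajectory(
        closed,
        open_,
        n_frames=int(p["n_frames"]),
        collapse_frame=int(p["collapse_frame"]),
        noise_sd=float(p["noise_sd"]),
        seed=seed + 1,
        dt_ns=float(p["dt_ns"]),
    )
    write_structure(closed, outdir / "reference_closed.pdb")
    write_structure(open_, outdir / "reference_open.pdb")
    write_trajectory(traj, outdir / "trajectory.tsv", format="flat_table")

    u = p["umbrella"]
    potential = table_potential(u["potential_table"]["xs"], u["potential_table"]["ys"])
    dataset = generate_umbrella_dataset(
        potential,
        n_windows=int(u["n_windows"]),
        spacing=float(u["spacing"]),
        force_const=float(u["force_const"]),
        n_samples=int(u["n_samples"]),
        temperature=float(u["temperature"]),
        seed=seed + 2,
    )
    meta_rows = []
    for i, w in enumerate(dataset.windows):
        fname = f"window_{i:03d}.tsv"
        pd.DataFrame(
            {"sample_index": np.arange(len(w.samples)), "xi_nm": w.samples}
        ).to_csv(outdir / fname, sep="\t", index=False)
        meta_rows.append(
            {
                "filename": fname,
                "center_nm": w.center,
                "force_const_kj_mol_nm2": w.force_const,
                "temperature_K": w.temperature,
            }
        )
    pd.DataFrame(meta_rows).to_csv(outdir / "windows.tsv", sep="\t", index=False)
    return [
        "reference_closed.pdb",
        "reference_open.pdb",
        "trajectory.tsv",
        "windows.tsv",
    ] + [r["filename"] for r in meta_rows]


def _load_synth_inputs(outdir: Path):
    closed_p = outdir / "reference_closed.pdb"
    traj_p = outdir / "trajectory.tsv"
    for q in (closed_p, outdir / "reference_open.pdb", traj_p):
        if not q.exists():
            raise ConfigurationError(
                f"missing input {q}; run the synth stage first"
            )
    closed = read_structure(closed_p)
    open_ = read_structure(outdir / "reference_open.pdb")
    traj = read_trajectory(traj_p, closed, format="flat_table")
    return closed, open_, traj


def _stage_activation(cfg: dict, outdir: Path) -> list:
    closed, open_, traj = _load_synth_inputs(outdir)
    outputs = []
    refs = {
        "ionic_lock": (IONIC_LOCK_PAIR, "distance_r173_e318.csv"),
        "tm5_tm6": (TM5_TM6_PAIR, "distance_q262_e318.csv"),
    }
    for _, ((a, b), fname) in refs.items():
        series = ca_distance_series(traj, a, b)
        series.to_frame().to_csv(outdir / fname, index=False, float_format="%.6g")
        outputs.append(fname)
    states = a100_series(traj)
    states.to_frame().to_csv(outdir / "a100.csv", index=False, float_format="%.6g")
    outputs.append("a100.csv")
    rmsd = rmsd_series(traj, closed, Selection(mode="ca"))
    rmsd.to_csv(outdir / "rmsd.csv", index=False, float_format="%.6g")
    outputs.append("rmsd.csv")
    return outputs


def _stage_landscape(cfg: dict, outdir: Path) -> list:
    closed, open_, traj = _load_synth_inputs(outdir)
    sel = loop_excluded_selection()
    aligned = superpose_trajectory(traj, sel)
    model = fit_pca(aligned, sel)
    proj = project(aligned, model, n_components=2)
    k_cfg = cfg["landscape"].get("k", "auto")
    k = choose_k(proj, seed=int(cfg["seed"])) if k_cfg == "auto" else int(k_cfg)
    result = kmeans_cluster(proj, k=k, seed=int(cfg["seed"]))

    df = pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "time_ns": traj.times,
            "PC1": proj[:, 0],
            "PC2": proj[:, 1],
            "cluster": result.labels,
        }
    )
    df.to_csv(outdir / "projection.csv", index=False, float_format="%.6g")
    pd.DataFrame(
        {
            "mode": np.arange(len(model.eigenvalues)),
            "eigenvalue_A2_amu": model.eigenvalues,
        }
    ).to_csv(outdir / "eigenvalues.csv", index=False, float_format="%.6g")

    references = {"closed": closed, "open": open_}
    report = {"k": k, "clusters": []}
    outputs = ["projection.csv", "eigenvalues.csv"]
    for c in range(k):
        frame_idx = int(result.centroid_frames[c])
        centroid = aligned.frame(frame_idx)
        fname = f"centroid_{c}.pdb"
        write_structure(centroid, outdir / fname)
        outputs.append(fname)
        rmsds, nearest = compare_to_references(centroid, references, sel)
        shift = tm6_outward_shift(centroid, closed, TM6_RANGE)
        report["clusters"].append(
            {
                "cluster": c,
                "centroid_frame": frame_idx,
                "n_frames": int(np.sum(result.labels == c)),
                "ref_rmsd_A": {n: _fmt(v) for n, v in rmsds.items()},
                "nearest_reference": nearest,
                "tm6_outward_shift_A": _fmt(shift),
            }
        )
    _write_json(report, outdir / "landscape.json")
    outputs.append("landscape.json")
    return outputs


def read_umbrella_dataset(meta_path, temperature_override: float | None = None) -> UmbrellaDataset:
    """Load per-window sample tables via a metadata TSV.

    The metadata file lists (filename, center_nm, force_const_kj_mol_nm2,
    temperature_K); sample files are two-column TSVs (index, ξ in nm),
    mirroring common umbrella-sampling tooling layouts.
    """
    meta_path = Path(meta_path)
    if not meta_path.exists():
        raise ConfigurationError(f"missing umbrella metadata file: {meta_path}")
    meta = pd.read_csv(meta_path, sep="\t")
    windows = []
    for _, row in meta.iterrows():
        sample_path = meta_path.parent / str(row["filename"])
        if not sample_path.exists():
            raise ConfigurationError(f"missing window sample file: {sample_path}")
        table = pd.read_csv(sample_path, sep="\t")
        temp = (
            temperature_override
            if temperature_override is not None
            else float(row.get("temperature_K", DEFAULT_TEMPERATURE))
        )
        windows.append(
            UmbrellaWindow(
                center=float(row["center_nm"]),
                force_const=float(row["force_const_kj_mol_nm2"]),
                samples=table.iloc[:, 1].to_numpy(dtype=float),
                temperature=temp,
            )
        )
    return UmbrellaDataset(windows=windows)


def _stage_pmf(cfg: dict, outdir: Path) -> list:
    p = cfg["pmf"]
    dataset = read_umbrella_dataset(outdir / "windows.tsv")
    profile = bayesian_bootstrap(
        dataset,
        n_boot=int(p["n_boot"]),
        seed=int(cfg["seed"]),
        n_bins=int(p["n_bins"]),
    )
    profile = zero_to_bulk(profile, tuple(p["bulk_region"]))
    pd.DataFrame(
        {
            "bin_center_nm": profile.bin_centers,
            "F_kcal_mol": profile.free_energy,
            "stderr_kcal_mol": profile.stderr,
        }
    ).to_csv(outdir / "pmf.csv", index=False, float_format="%.6g")

    state = p.get("state_label", "open")
    site_bfe = {
        site: binding_free_energy(profile, tuple(region), site_label=site, state_label=state)
        for site, region in p["site_regions"].items()
    }
    report = {
        "state": state,
        "temperature_K": float(p["temperature"]),
        "bulk_region_nm": list(p["bulk_region"]),
        "sites": {
            s: {"dg_kcal_mol": _fmt(b.dg), "sd_kcal_mol": _fmt(b.sd)}
            for s, b in site_bfe.items()
        },
    }
    if {"OBP", "EBP"} <= set(site_bfe):
        value, sd = ddg(site_bfe["EBP"], site_bfe["OBP"])
        ratio = occupancy_ratio(value, float(p["temperature"]))
        report["ddg_ebp_obp_kcal_mol"] = _fmt(value)
        report["ddg_sd_kcal_mol"] = _fmt(sd)
        report["occupancy_ratio_obp_over_ebp"] = _fmt(ratio.ratio)
        report["orders_of_magnitude"] = ratio.orders_of_magnitude
    hist = build_histograms(dataset, n_bins=int(p["n_bins"]))
    report["min_adjacent_shared_bins"] = int(
        min(o["shared_bins"] for o in hist.overlaps)
    ) if hist.overlaps else None
    _write_json(report, outdir / "pmf_report.json")
    return ["pmf.csv", "pmf_report.json"]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "activation": _stage_activation,
    "landscape": _stage_landscape,
    "pmf": _stage_pmf,
}


def run_pipeline(config: dict) -> dict:
    """Execute the configured stage(s); returns the manifest.

    ``stage="all"`` runs synth → activation → landscape → pmf.  Any stage
    error propagates (the CLI converts it to a nonzero exit status).
    """
    cfg = _deep_update(DEFAULT_CONFIG, config or {})
    if cfg["stage"] not in STAGES + ("all",):
        raise ConfigurationError(f"unknown stage {cfg['stage']!r}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = STAGES if cfg["stage"] == "all" else (cfg["stage"],)
    manifest = {
        "package": "statescan",
        "version": __version__,
        "seed": int(cfg["seed"]),
        "config": cfg,
        "stages": [],
        "outputs": {},
    }
    for stage in stages:
        t0 = time.perf_counter()
        log.info("stage=%s starting (seed=%s)", stage, cfg["seed"])
        outputs = _STAGE_FUNCS[stage](cfg, outdir)
        dt = time.perf_counter() - t0
        log.info("stage=%s done in %.2fs outputs=%d", stage, dt, len(outputs))
        manifest["stages"].append({"stage": stage, "outputs": outputs})
        for fname in outputs:
            manifest["outputs"][fname] = _sha256(outdir / fname)
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def make_table1_report(entries: dict, temperature: float = DEFAULT_TEMPERATURE) -> pd.DataFrame:
    """Binding-free-energy summary table from per-system OBP/EBP pairs.

    ``entries`` maps a system name (e.g. ``"SERO/open"``) to a mapping with
    ``"OBP"`` and ``"EBP"`` :class:`~statescan.pmf.BindingFreeEnergy`
    values.  Emits one row per system with ΔG for both subpockets, the
    ΔΔG_EBP−OBP column, the Boltzmann occupancy ratio p_OBP/p_EBP and its
    order of magnitude.
    """
    missing = [
        f"{system}:{site}"
        for system, pair in entries.items()
        for site in ("OBP", "EBP")
        if site not in pair
    ]
    if missing:
        raise ConfigurationError(f"incomplete OBP/EBP pairs: {', '.join(missing)}")
    rows = []
    for system, pair in entries.items():
        value, sd = ddg(pair["EBP"], pair["OBP"])
        ratio = occupancy_ratio(value, temperature)
        rows.append(
            {
                "system": system,
                "dG_OBP_kcal_mol": pair["OBP"].dg,
                "dG_EBP_kcal_mol": pair["EBP"].dg,
                "ddG_EBP_OBP_kcal_mol": value,
                "ddG_sd_kcal_mol": sd,
                "p_OBP_over_p_EBP": ratio.ratio,
                "orders_of_magnitude": ratio.orders_of_magnitude,
            }
        )
    return pd.DataFrame(rows)
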