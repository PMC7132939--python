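"""File formats, run configuration and the end-to-end pipeline.

Catalogs travel as UTF-8 comma-separated CSV with a header and "." decimals
(columns: id, x_um, y_um, z_um, volume_um3, layer, compartment, docked,
tubules, clathrin, stack_id; flags as 0/1); label stacks as multi-page TIFF
(one page per Z section, integer labels); configuration and reports as JSON.
Coordinates are 0-based voxel indices internally and physical μm externally.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .geometry import Box3D, StackGeometry
from .morphometry import ShrinkageFactors, apply_shrinkage_correction
from .spatial import InsufficientPointsError, PointPattern3D, envelope_test
from .stats import (
    compartment_percentages,
    concentration_ratio,
    fit_lognormal,
    size_summary,
)
from .stereology import (
    CavalieriGrid,
    CountingFrame,
    cavalieri_volume_fraction,
    estimate_density,
)
from .synthetic import (
    CATALOG_COLUMNS,
    CatalogSpec,
    ProcessSpec,
    VoxelStack,
    generate_catalog,
    render_label_stack,
)

FLAG_COLUMNS = ("docked", "tubules", "clathrin")


# ------------------------------------------------------------------- catalog

def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.loc[:, list(CATALOG_COLUMNS)].copy()
    for c in FLAG_COLUMNS:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path} is missing columns {sorted(missing)}")
    for c in FLAG_COLUMNS:
        df[c] = df[c].astype(bool)
    df["id"] = df["id"].astype(np.int64)
    df["stack_id"] = df["stack_id"].astype(np.int64)
    return df


def write_windows(windows: dict, path: str | Path) -> None:
    payload = {
        str(k): {"lo": list(v[0]), "hi": list(v[1])} for k, v in windows.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_windows(path: str | Path) -> dict[int, Box3D]:
    payload = json.loads(Path(path).read_text())
    return {
        int(k): Box3D(tuple(v["lo"]), tuple(v["hi"])) for k, v in payload.items()
    }


# --------------------------------------------------------------------- TIFF

def write_stack(stack: VoxelStack, path: str | Path) -> None:
    """Multi-page TIFF, one page per Z section, plus voxel metadata."""
    meta = {
        "voxel_size_nm": list(stack.geometry.voxel_size_nm),
        "origin_um": list(stack.geometry.origin_um),
    }
    tifffile.imwrite(path, stack.labels, metadata=meta)


def read_stack(
    path: str | Path, voxel_size_nm: tuple[float, float, float] | None = None
) -> VoxelStack:
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if labels.ndim == 2:
        labels = labels[None, ...]
    if voxel_size_nm is None:
        voxel_size_nm = tuple(meta.get("voxel_size_nm", (20.0, 20.0, 20.0)))
    origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
    nz, ny, nx = labels.shape
    geom = StackGeometry(
        shape=(nx, ny, nz), voxel_size_nm=voxel_size_nm, origin_um=origin
    )
    return VoxelStack(labels=labels, geometry=geom)


# -------------------------------------------------------------------- config

DEFAULT_VOLUME_FRACTIONS = {
    # % of neuropil volume per compartment (fixed constants from prior
    # stereology on the same tissue; used for concentration ratios)
    "dendrite": 38.50,
    "axon": 22.81,
    "nonsynaptic": 38.69,
}


@dataclass
class RunConfig:
    """Schema-validated pipeline configuration (JSON-serializable)."""

    seed: int = 0
    out_dir: str = "results"
    # inputs: either simulate, or read these catalog/window files
    catalog_path: str | None = None
    windows_path: str | None = None
    # simulation
    n_stacks: int = 29
    intensity: float = 0.21
    lognormal_mu: float = -5.1375
    lognormal_sigma: float = 0.9173
    compartment_probs: tuple = (0.3914, 0.1587, 0.0229, 0.4270)
    flag_probs: tuple = (0.1816, 0.0666, 0.1974)
    # counting frame: shrink each stack window by this margin (μm) per face
    frame_margin_um: float = 0.0
    # Cavalieri
    grid_spacing_nm: float = 632.0
    section_step: int = 40
    render_voxel_nm: float = 40.0
    render_stacks: bool = False
    # spatial
    envelope_nsim: int = 100
    envelope_min_points: int = 25
    # shrinkage
    shrinkage_linear: float = 0.90

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_stacks <= 0:
            raise ValueError("n_stacks must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.envelope_nsim < 1:
            raise ValueError("envelope_nsim must be >= 1")
        if not (0 < self.shrinkage_linear <= 1):
            raise ValueError("shrinkage_linear must be in (0, 1]")
        if self.catalog_path is not None and not Path(self.catalog_path).exists():
            raise FileNotFoundError(f"catalog not found: {self.catalog_path}")
        if self.windows_path is not None and not Path(self.windows_path).exists():
            raise FileNotFoundError(f"windows file not found: {self.windows_path}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# ------------------------------------------------------------------ pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain and write the result bundle.

    Stages, in order: obtain catalog (simulate or load) → shrinkage-corrected
    counting-frame densities → (optional) phantom rendering + Cavalieri
    volume fractions → compartment tables and concentration ratios → size
    summaries and log-normal fit → per-stack spatial randomness tests.
    Identical config + seed gives bit-identical summary outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.perf_counter()

    def log(stage: str) -> None:
        log_lines.append(f"{stage}: {time.perf_counter() - t0:.2f}s elapsed")

    # --- catalog
    if config.catalog_path is not None:
        catalog = read_catalog(config.catalog_path)
        if config.windows_path is not None:
            windows = read_windows(config.windows_path)
        else:
            windows = _bounding_windows(catalog)
    else:
        spec = CatalogSpec(
            n_stacks=config.n_stacks,
            lognormal_mu=config.lognormal_mu,
            lognormal_sigma=config.lognormal_sigma,
            compartment_probs=tuple(config.compartment_probs),
            flag_probs=tuple(config.flag_probs),
        )
        process = ProcessSpec.csr(config.intensity)
        catalog = generate_catalog(spec, process, seed=config.seed)
        windows = {k: Box3D(v[0], v[1]) for k, v in catalog.attrs["windows"].items()}
    write_catalog(catalog, out / "catalog.csv")
    write_windows({k: (w.lo, w.hi) for k, w in windows.items()}, out / "windows.json")
    log("catalog")

    # --- density (shrinkage-corrected frame volumes)
    factors = ShrinkageFactors.from_linear(config.shrinkage_linear)
    frames = {}
    for sid, w in windows.items():
        lo = np.asarray(w.lo) + config.frame_margin_um
        hi = np.asarray(w.hi) - config.frame_margin_um
        frames[sid] = CountingFrame(Box3D(tuple(lo), tuple(hi)))
    dens = estimate_density(catalog, frames)
    per_stack = dens.per_stack.copy()
    per_stack["frame_volume_um3"] = apply_shrinkage_correction(
        per_stack["frame_volume_um3"].to_numpy(), "volume", factors
    )
    per_stack["density"] = per_stack["count"] / per_stack["frame_volume_um3"]
    density_rows = per_stack.assign(scope="stack")
    layer_rows = dens.per_layer.rename(columns={"mean": "density"}).assign(
        scope="layer", stack_id="", count="", frame_volume_um3=""
    )
    pooled_row = pd.DataFrame(
        [{
            "scope": "pooled", "stack_id": "", "layer": "I-VI", "count": "",
            "frame_volume_um3": "", "density": dens.grand_mean,
            "sem": dens.grand_sem, "n_stacks": len(per_stack),
        }]
    )
    density_csv = pd.concat([density_rows, layer_rows, pooled_row], ignore_index=True)
    density_csv.to_csv(out / "density.csv", index=False)
    log("density")

    # --- Cavalieri volume fraction of the objects themselves
    volfrac_rows = []
    if config.render_stacks:
        grid = CavalieriGrid(config.grid_spacing_nm, config.section_step)
        for sid, w in sorted(windows.items()):
            sub = catalog[catalog["stack_id"] == sid]
            sides = w.sides
            shape = tuple(
                int(np.ceil(s * 1000.0 / config.render_voxel_nm)) for s in sides
            )
            geom = StackGeometry(
                shape=shape,
                voxel_size_nm=(config.render_voxel_nm,) * 3,
                origin_um=w.lo,
            )
            stack = render_label_stack(sub, geom, seed=config.seed)
            ids = sub["id"].tolist()
            frac = (
                cavalieri_volume_fraction(stack, grid, ids) if ids else 0.0
            )
            volfrac_rows.append(
                {"stack_id": sid, "layer": sub["layer"].iloc[0] if len(sub) else "",
                 "volume_fraction": frac}
            )
    pd.DataFrame(
        volfrac_rows, columns=["stack_id", "layer", "volume_fraction"]
    ).to_csv(out / "volfrac.csv", index=False)
    log("volfrac")

    # --- compartment tables + concentration ratios
    table1 = compartment_percentages(catalog)
    table1.round(2).to_csv(out / "table1_compartments.csv", index=False)
    docked = catalog[catalog["docked"]]
    if len(docked):
        table2 = compartment_percentages(docked)
    else:
        table2 = pd.DataFrame(columns=table1.columns)
    table2.round(2).to_csv(out / "table2_docked.csv", index=False)
    table3 = size_summary(catalog)
    table3.to_csv(out / "table3_sizes.csv", index=False)

    pooled = table1.iloc[-1]
    pct = {
        "dendrite": pooled["dendrite_pct"],
        "axon": pooled["excitatory_axon_pct"] + pooled["inhibitory_axon_pct"],
        "nonsynaptic": pooled["nonsynaptic_pct"],
    }
    ratios = [
        concentration_ratio(pct[c], DEFAULT_VOLUME_FRACTIONS[c], c)
        for c in ("dendrite", "axon", "nonsynaptic")
    ]
    pd.DataFrame([asdict(r) for r in ratios]).to_csv(
        out / "concentration_ratios.csv", index=False
    )
    log("compartments")

    # --- size distribution
    fit = fit_lognormal(catalog["volume_um3"].to_numpy())
    (out / "lognormal_fit.json").write_text(
        json.dumps(
            {
                "mu": fit.mu, "sigma": fit.sigma, "n": fit.n,
                "log_likelihood": fit.log_likelihood,
                "ks_statistic": fit.ks_statistic, "ks_pvalue": fit.ks_pvalue,
                "mean_um3": fit.mean, "median_um3": fit.median,
            },
            indent=2, sort_keys=True,
        )
    )
    log("sizes")

    # --- spatial randomness per stack
    env_dir = out / "envelopes"
    env_dir.mkdir(exist_ok=True)
    verdicts = []
    ss = np.random.SeedSequence(config.seed).spawn(len(windows) + 1)[-1]
    env_seeds = ss.generate_state(len(windows))
    for j, (sid, w) in enumerate(sorted(windows.items())):
        sub = catalog[catalog["stack_id"] == sid]
        pts = sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        pat = PointPattern3D(pts, w)
        try:
            res = envelope_test(
                pat, nsim=config.envelope_nsim, seed=int(env_seeds[j] % (2**31)),
                min_points=config.envelope_min_points,
            )
        except InsufficientPointsError:
            verdicts.append({"stack_id": sid, "n": pat.n, "verdict": "excluded"})
            continue
        (env_dir / f"stack_{sid}.json").write_text(
            json.dumps(res.to_dict(), indent=2, sort_keys=True)
        )
        verdicts.append({"stack_id": sid, "n": pat.n, "verdict": res.verdict.value})
    pd.DataFrame(verdicts).to_csv(out / "spatial_verdicts.csv", index=False)
    log("spatial")

    config.to_json(out / "run_config.json")
    log_lines.append(f"mvbkit version {__version__}, seed {config.seed}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "catalog": catalog,
        "density": dens,
        "lognormal_fit": fit,
        "verdicts": verdicts,
        "out_dir": str(out),
    }


def _bounding_windows(catalog: pd.DataFrame) -> dict[int, Box3D]:
    """Fallback windows: the axis-aligned bounding box of each stack's
    points, padded by one mean nearest-neighbour spacing."""
    windows = {}
    for sid in sorted(catalog["stack_id"].unique()):
        sub = catalog[catalog["stack_id"] == sid]
        pts = sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        pad = max(float(np.mean(hi - lo)) / max(len(pts), 1) ** (1 / 3), 1e-6)
        windows[int(sid)] = Box3D(tuple(lo - pad), tuple(hi + pad))
    return windows
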