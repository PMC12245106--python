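"""Volume I/O, run configuration and the end-to-end pipeline driver.

Volumes travel as multi-channel TIFF with a JSON description (channel
roles, voxel size, seed) in the image description tag; tables as CSV;
summaries as JSON.  Unit conventions across every interface: lengths in
um, doses in uM, intensities in arbitrary units; voxel indices are
0-based (z, y, x) internally, physical (x, y, z) um in outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .dose_response import HillParams, fit_hill
from .hc_imaging import process_volume, records_to_frame
from .ht_platereader import ht_hill_fit
from .packing import LatticeSpec
from .synth import (
    DEFAULT_NOISE,
    DEFAULT_VOXEL_SIZE,
    VolumeImage,
    build_void_lattice,
    simulate_volume,
    simulate_wellscan,
)

log = logging.getLogger("bhicc")

_CHANNELS = ("green", "blue", "red")
SCHEMA_VERSION = 1


def write_volume(path, volume: VolumeImage, metadata: dict | None = None) -> None:
    """Write a 3-channel volume as TIFF, axes CZYX, metadata as JSON description."""
    stack = np.stack([volume.green, volume.blue, volume.red]).astype(np.float32)
    desc = {
        "schema_version": SCHEMA_VERSION,
        "bhicc_version": __version__,
        "channels": list(_CHANNELS),
        "voxel_size_um": list(volume.voxel_size),
        **(metadata or {}),
    }
    tifffile.imwrite(path, stack, description=json.dumps(desc), metadata={"axes": "CZYX"})


def read_volume(path) -> tuple[VolumeImage, dict]:
    """Read a 3-channel TIFF volume written by :func:`write_volume`.

    Returns ``(volume, metadata)``.  Raises a format error naming the
    missing field when channels or voxel size are absent.
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    if "voxel_size_um" not in meta:
        raise ValueError("volume file missing field 'voxel_size_um'")
    if meta.get("channels") != list(_CHANNELS):
        raise ValueError("volume file missing field 'channels' (green, blue, red)")
    if meta.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {meta.get('schema_version')}")
    if stack.ndim != 4 or stack.shape[0] != 3:
        raise ValueError(f"expected 3-channel CZYX stack, got shape {stack.shape}")
    vol = VolumeImage(
        green=stack[0], blue=stack[1], red=stack[2],
        voxel_size=tuple(float(v) for v in meta["voxel_size_um"]),
    )
    return vol, meta


@dataclass
class RunConfig:
    """Configuration of one simulate -> analyse run."""

    seed: int = 0
    out_dir: str = "bhicc_out"
    mode: str = "hc"                      # "hc", "ht" or "both"
    # lattice / volume
    void_diameter: float = 250.0
    container_diameter: float = 2000.0
    layers: int = 1
    jitter_sd: float = 0.0
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    cap_diameter: float = 45.0
    diam_mean: float = 179.2
    diam_sd: float = 9.76
    # dose design
    doses: tuple = (0.0, 10.0, 20.0, 50.0, 100.0, 200.0)
    hill: dict = field(default_factory=lambda: {"ic50": 18.92, "n": 2.807, "top": 1.0, "bottom": 0.0})
    wells_per_dose: int = 4
    points_per_well: int = 36
    # analysis
    green_gate: float = 2000.0
    threshold_method: str = "otsu"
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stamp(self) -> dict:
        return {"bhicc_version": __version__, "seed": self.seed, "config_hash": self.digest()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured screening workflow and write all artifacts.

    HC mode: simulate a volume, run the imaging pipeline, fit the Hill
    curve to per-spheroid viabilities.  HT mode: simulate well scans, run
    the plate-reader path.  Every artifact carries (version, seed, config
    hash).  Returns a result bundle dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config.stamp()
    hill = HillParams(**config.hill)
    bundle: dict = {"stamp": stamp, "out_dir": str(out)}

    if config.mode in ("hc", "both"):
        spec = LatticeSpec(
            void_diameter=config.void_diameter,
            container_diameter=config.container_diameter,
            layers=config.layers,
        )
        lattice = build_void_lattice(spec, jitter_sd=config.jitter_sd, seed=config.seed)
        log.info("lattice built: %d voids in %d layer(s)", len(lattice), config.layers)
        all_records = []
        for i, dose in enumerate(config.doses):
            vol, truth = simulate_volume(
                lattice, config.diam_mean, config.diam_sd, dose, hill,
                cap_diameter=config.cap_diameter, noise=config.noise,
                voxel_size=tuple(config.voxel_size), seed=config.seed + i + 1,
            )
            records, cmap = process_volume(
                vol, expected_diameter=config.void_diameter,
                threshold_method=config.threshold_method,
            )
            frame = records_to_frame(records)
            frame.insert(0, "dose_uM", dose)
            all_records.append(frame)
            cmap.entries.to_csv(out / f"circle_map_dose{dose:g}.csv", index=False)
            log.info("dose %g uM: %d ROIs, %d scored", dose, len(records),
                     int(frame["viability"].notna().sum()))
        hc_table = pd.concat(all_records, ignore_index=True)
        hc_table.to_csv(out / "spheroid_records.csv", index=False)
        scored = hc_table.dropna(subset=["viability"])
        hc_fit = fit_hill(scored["dose_uM"].to_numpy(float), scored["viability"].to_numpy(float))
        bundle["hc"] = {
            "records_csv": str(out / "spheroid_records.csv"),
            "hill_fit": _fit_to_dict(hc_fit),
        }
        with open(out / "hc_hill_fit.json", "w") as fh:
            json.dump({**stamp, **bundle["hc"]["hill_fit"]}, fh, indent=2)

    if config.mode in ("ht", "both"):
        scan = simulate_wellscan(
            config.doses, hill, points_per_well=config.points_per_well,
            wells_per_dose=config.wells_per_dose, seed=config.seed,
        )
        scan.to_csv(out / "wellscan.csv", index=False)
        ht_fit = ht_hill_fit(scan, green_threshold=config.green_gate)
        log.info("HT path: %d scan rows, IC50 %.3g uM", len(scan), ht_fit.params.ic50)
        bundle["ht"] = {
            "wellscan_csv": str(out / "wellscan.csv"),
            "hill_fit": _fit_to_dict(ht_fit),
        }
        with open(out / "ht_hill_fit.json", "w") as fh:
            json.dump({**stamp, **bundle["ht"]["hill_fit"]}, fh, indent=2)

    with open(out / "run_summary.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2)
    return bundle


def _fit_to_dict(fit) -> dict:
    return {
        "ic50_uM": fit.params.ic50,
        "hill_n": fit.params.n,
        "top": fit.params.top,
        "bottom": fit.params.bottom,
        "r_squared": fit.r_squared,
        "n_obs": fit.n_obs,
        "extrapolated": fit.extrapolated,
        "degenerate": fit.degenerate,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
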