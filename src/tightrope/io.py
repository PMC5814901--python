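"""File-format round trips: TIFF movies, spot/census/survival CSV, JSON, YAML."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .coloc import CensusTable
from .detection import ChannelRegistration, MovieStack, Spot, TightropeGeometry
from .survival import SurvivalRecord

__all__ = [
    "write_movie", "read_movie",
    "write_spots", "read_spots",
    "write_registration", "read_registration",
    "write_geometry", "read_geometry",
    "write_census", "read_census",
    "write_survival", "read_survival",
    "write_config_yaml", "read_config_yaml",
]

SPOT_COLUMNS = ["movie", "channel", "frame", "x_px", "y_px", "intensity", "sigma_px"]


def write_movie(movie: MovieStack, directory, stem: str = "movie") -> list[Path]:
    """Write one multi-page TIFF per channel (frame-major) plus metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch, stack in movie.channels.items():
        p = directory / f"{stem}_ch{ch}.tif"
        tifffile.imwrite(p, stack.astype(np.float32))
        paths.append(p)
    meta = {"pixel_size_nm": movie.pixel_size_nm,
            "frame_interval_s": movie.frame_interval_s,
            "channels": sorted(movie.channels)}
    (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
    return paths


def read_movie(directory, stem: str = "movie") -> MovieStack:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    channels = {ch: tifffile.imread(directory / f"{stem}_ch{ch}.tif").astype(float)
                for ch in meta["channels"]}
    return MovieStack(channels=channels, pixel_size_nm=meta["pixel_size_nm"],
                      frame_interval_s=meta["frame_interval_s"])


def spots_to_frame(spots: list[Spot], movie: str = "") -> pd.DataFrame:
    return pd.DataFrame([{"movie": movie, "channel": s.channel, "frame": s.frame,
                          "x_px": s.x, "y_px": s.y, "intensity": s.intensity,
                          "sigma_px": s.sigma_fit} for s in spots],
                        columns=SPOT_COLUMNS)


def frame_to_spots(df: pd.DataFrame) -> list[Spot]:
    return [Spot(x=float(r.x_px), y=float(r.y_px), intensity=float(r.intensity),
                 sigma_fit=float(r.sigma_px), frame=int(r.frame),
                 channel=str(r.channel)) for r in df.itertuples()]


def write_spots(spots: list[Spot], path, movie: str = "") -> None:
    spots_to_frame(spots, movie).to_csv(path, index=False)


def read_spots(path) -> list[Spot]:
    try:
        df = pd.read_csv(path, dtype={"channel": str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed spot CSV {path}: {exc}") from exc
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spot CSV {path} missing columns {missing}")
    extra = [c for c in df.columns if c not in SPOT_COLUMNS]
    if extra:
        warnings.warn(f"spot CSV {path} has extra columns {extra}; preserved",
                      stacklevel=2)
    return frame_to_spots(df)


def write_registration(reg: ChannelRegistration, path) -> None:
    data = {"reference": reg.reference,
            "offsets": {ch: list(off) for ch, off in reg.offsets.items()},
            "residual_rms": reg.residual_rms}
    Path(path).write_text(json.dumps(data, indent=2))


def read_registration(path) -> ChannelRegistration:
    data = json.loads(Path(path).read_text())
    return ChannelRegistration(
        reference=data["reference"],
        offsets={ch: tuple(off) for ch, off in data["offsets"].items()},
        residual_rms=data.get("residual_rms", {}))


def write_geometry(geom: TightropeGeometry, path) -> None:
    data = {"endpoints": geom.endpoints.tolist(),
            "pixel_size_nm": geom.pixel_size_nm,
            "tightrope_id": geom.tightrope_id}
    Path(path).write_text(json.dumps(data, indent=2))


def read_geometry(path) -> TightropeGeometry:
    data = json.loads(Path(path).read_text())
    return TightropeGeometry(endpoints=np.array(data["endpoints"]),
                             pixel_size_nm=data["pixel_size_nm"],
                             tightrope_id=data.get("tightrope_id", 0))


def write_census(census: CensusTable, path) -> None:
    df = census.table.copy()
    df["total"] = census.total
    df["n_flowcells"] = census.n_flow_cells
    df.to_csv(path, index=False, float_format="%.6f")


def read_census(path) -> CensusTable:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"census CSV {path} is empty (census cannot be empty)")
    total = int(df["total"].iloc[0])
    n_fc = int(df["n_flowcells"].iloc[0])
    return CensusTable(table=df.drop(columns=["total", "n_flowcells"]),
                       total=total, n_flow_cells=n_fc)


SURVIVAL_COLUMNS = ["strain", "dose_Jm2", "dilution", "colony_count", "replicate"]


def write_survival(records: list[SurvivalRecord], path) -> None:
    pd.DataFrame([{"strain": r.strain, "dose_Jm2": r.dose_J_m2,
                   "dilution": r.dilution, "colony_count": r.colony_count,
                   "replicate": r.replicate} for r in records],
                 columns=SURVIVAL_COLUMNS).to_csv(path, index=False)


def read_survival(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival CSV {path} missing columns {missing}")
    extra = [c for c in df.columns if c not in SURVIVAL_COLUMNS]
    if extra:
        warnings.warn(f"survival CSV {path} has extra columns {extra}; preserved",
                      stacklevel=2)
    return [SurvivalRecord(strain=str(r.strain), dose_J_m2=float(r.dose_Jm2),
                           dilution=float(r.dilution),
                           colony_count=int(r.colony_count),
                           replicate=int(r.replicate)) for r in df.itertuples()]


def write_config_yaml(config_dict: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_dict, sort_keys=True))


def read_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
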