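"""File-format helpers: YAML schedules, PNG frame sequences, CSV logs."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .analytics import TimeBin, bins_from_frame, bins_to_frame
from .stimulus import GratingParams

__all__ = [
    "load_schedule_yaml",
    "save_schedule_yaml",
    "write_frames",
    "read_frames",
    "load_bins_csv",
    "save_bins_csv",
]


def _params_from_dict(d: dict) -> GratingParams:
    known = {k: d[k] for k in ("omega", "n_gratings", "spacing", "thickness",
                               "center_radius", "blank") if k in d}
    return GratingParams(**known)


def load_schedule_yaml(path) -> list[TimeBin]:
    """Load a stimulus schedule from YAML.

    Layout: a top-level ``bins`` list; each entry has ``tb``, ``tbn``, an
    optional ``label`` and any GratingParams fields, merged over an optional
    top-level ``defaults`` mapping.
    """
    doc = yaml.safe_load(Path(path).read_text())
    defaults = doc.get("defaults", {}) if isinstance(doc, dict) else {}
    entries = doc["bins"] if isinstance(doc, dict) else doc
    bins = []
    for e in entries:
        merged = {**defaults, **e}
        bins.append(
            TimeBin(
                tb=float(merged.pop("tb")),
                tbn=float(merged.pop("tbn")),
                label=str(merged.pop("label", "")),
                stimulus=_params_from_dict(merged),
            )
        )
    return bins


def save_schedule_yaml(bins: Sequence[TimeBin], path) -> None:
    entries = []
    for b in bins:
        entries.append(
            {
                "tb": b.tb,
                "tbn": b.tbn,
                "label": b.label,
                "omega": b.stimulus.omega,
                "n_gratings": b.stimulus.n_gratings,
                "spacing": b.stimulus.spacing,
                "thickness": b.stimulus.thickness,
                "center_radius": b.stimulus.center_radius,
                "blank": b.stimulus.blank,
            }
        )
    Path(path).write_text(yaml.safe_dump({"bins": entries}, sort_keys=False))


def write_frames(frames: Sequence[np.ndarray], out_dir, prefix: str = "frame") -> list[Path]:
    """Write a frame sequence as zero-padded PNGs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        img = f
        if img.dtype != np.uint8:
            img = np.clip(np.asarray(img, dtype=float) * 255, 0, 255).astype(np.uint8)
        p = out / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


def read_frames(src_dir, pattern: str = "*.png") -> list[np.ndarray]:
    """Read an ordered PNG frame sequence from a directory."""
    paths = sorted(Path(src_dir).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no frames matching {pattern} in {src_dir}")
    return [iio.imread(p) for p in paths]


def load_bins_csv(path, base: GratingParams | None = None) -> list[TimeBin]:
    return bins_from_frame(pd.read_csv(path), base=base)


def save_bins_csv(bins: Sequence[TimeBin], path) -> None:
    bins_to_frame(bins).to_csv(path, index=False)
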