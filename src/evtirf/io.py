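"""File formats: multi-page 16-bit TIFF per image, CSV tables, YAML config.

CSV dialect: header row, UTF-8, '.' decimal. TIFF pages are channels in panel
order. Writers are deterministic (no timestamps embedded) so identical runs
produce byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import SimulatedExperiment


def write_image_stack(path: Path, stack: np.ndarray) -> None:
    """Write a (C, H, W) float stack as multi-page 16-bit TIFF (clipped)."""
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_image_stack(path: Path) -> np.ndarray:
    """Read a multi-page TIFF back as a (C, H, W) float array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return arr.astype(float)


def write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_experiment(exp: SimulatedExperiment, out_dir: Path) -> dict:
    """Write images/, metadata.csv and ground_truth.csv; returns row counts."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for image_id, stack in exp.images.items():
        write_image_stack(img_dir / f"{image_id}.tiff", stack)
    write_csv(exp.metadata, out_dir / "metadata.csv")
    truth = exp.truth_frame()
    write_csv(truth, out_dir / "ground_truth.csv")
    return {"images": len(exp.images), "metadata_rows": len(exp.metadata),
            "truth_rows": len(truth)}
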