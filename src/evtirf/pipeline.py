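"""End-to-end orchestration: simulate -> detect -> classify -> test.

Every stage writes its CSV outputs under the run directory; a manifest records
the configuration hash, per-stage row counts and seeds. Identical
(config, seed) pairs reproduce identical images, tables and p-values.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import colocalize_all, count_evs, intensity_table
from .config import RunConfig
from .detect import DETECTION_COLUMNS, concat_nonempty, detect_stack
from .io import read_csv, read_image_stack, write_csv, write_experiment
from .seeding import substream
from .simulate import generate_experiment
from .stats import (
    frequency_distribution,
    ks_bootstrap_pvalue,
    median_fold,
    pearson_matrix,
    permutation_density_test,
)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stage_rows: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    status: str = "incomplete"

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
        tmp.replace(path)  # atomic at run end


def simulate_stage(config: RunConfig, out_dir: Path) -> dict:
    exp = generate_experiment(
        [(d.condition, d.n_images) for d in config.conditions],
        config.panel,
        config.imaging,
        config.seed,
        snr=config.snr,
    )
    return write_experiment(exp, out_dir)


def detect_stage(config: RunConfig, run_dir: Path) -> int:
    meta = read_csv(run_dir / "metadata.csv")
    parts = []
    for image_id in meta["image_id"]:
        stack = read_image_stack(run_dir / "images" / f"{image_id}.tiff")
        parts.append(
            detect_stack(stack, config.detection, config.imaging.pixel_size_um, image_id)
        )
    det = concat_nonempty(parts, DETECTION_COLUMNS)
    write_csv(det, run_dir / "detections.csv")
    return len(det)


def classify_stage(config: RunConfig, run_dir: Path) -> dict:
    meta = read_csv(run_dir / "metadata.csv")
    det = read_csv(run_dir / "detections.csv")
    records = colocalize_all(det, config.colocalization_radius_um, config.panel)
    counts = count_evs(records, meta, config.panel)
    write_csv(records, run_dir / "ev_records.csv")
    write_csv(counts, run_dir / "count_table.csv")

    # complete per-EV intensity table for the channel-correlation analysis
    images = {
        iid: read_image_stack(run_dir / "images" / f"{iid}.tiff")
        for iid in records["image_id"].unique()
    }
    itab = intensity_table(records, images, config.imaging.pixel_size_um)
    write_csv(itab, run_dir / "ev_intensities.csv")
    return {"ev_records": len(records), "count_rows": len(counts)}


def stats_stage(config: RunConfig, run_dir: Path) -> int:
    counts = read_csv(run_dir / "count_table.csv")
    itab = read_csv(run_dir / "ev_intensities.csv")
    rows = []
    for i, cmp_ in enumerate(config.comparisons):
        x = counts.loc[counts["condition"] == cmp_.a, "total"].to_numpy()
        y = counts.loc[counts["condition"] == cmp_.b, "total"].to_numpy()
        rng_ks = substream(config.seed, "stats.ks", cmp_.name)
        rng_den = substream(config.seed, "stats.density", cmp_.name)
        if "ks_bootstrap" in cmp_.tests:
            res = ks_bootstrap_pvalue(x, y, n_b=config.n_resamples, rng=rng_ks)
            rows.append(_result_row(cmp_.name, res, config.seed))
        if "density_permutation" in cmp_.tests:
            res = permutation_density_test(x, y, n_perm=config.n_resamples, rng=rng_den)
            rows.append(_result_row(cmp_.name, res, config.seed))
        if "median_fold" in cmp_.tests:
            mf = median_fold(x, y)
            rows.append(
                dict(comparison=cmp_.name, statistic="median_fold",
                     value=mf.value if mf.finite else float("nan"),
                     p_value=float("nan"), n_resamples=0, seed=config.seed,
                     n_a=len(x), n_b=len(y))
            )

    # per-condition frequency summaries
    freq_rows = []
    for d in config.conditions:
        vals = counts.loc[counts["condition"] == d.condition.label, "total"].to_numpy()
        fs = frequency_distribution(vals)
        freq_rows.append(
            dict(condition=d.condition.label, n_images=fs.n, median=fs.median,
                 zero_fraction=fs.zero_fraction)
        )
    write_csv(pd.DataFrame(freq_rows), run_dir / "frequency_summary.csv")

    if len(itab) >= 3:
        r, p = pearson_matrix(itab)
        write_csv(r.reset_index(names="channel"), run_dir / "pearson_r.csv")
        write_csv(p.reset_index(names="channel"), run_dir / "pearson_p.csv")

    results = pd.DataFrame(
        rows,
        columns=["comparison", "statistic", "value", "p_value", "n_resamples",
                 "seed", "n_a", "n_b"],
    )
    write_csv(results, run_dir / "test_results.csv")
    return len(results)


def _result_row(name: str, res, seed: int) -> dict:
    return dict(
        comparison=name, statistic=res.statistic_name, value=res.statistic_value,
        p_value=res.p_value, n_resamples=res.n_resamples, seed=seed,
        n_a=res.sample_sizes[0], n_b=res.sample_sizes[1],
    )


def run_pipeline(config: RunConfig, out_dir: Path) -> RunManifest:
    """Execute all stages in order; abort with a stage-labeled error on failure.

    Partial outputs are retained and the manifest marks the failed stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), package_version=__version__,
        seed=config.seed,
    )
    stages = [
        ("simulate", lambda: simulate_stage(config, out_dir)),
        ("detect", lambda: detect_stage(config, out_dir)),
        ("classify", lambda: classify_stage(config, out_dir)),
        ("stats", lambda: stats_stage(config, out_dir)),
    ]
    for name, fn in stages:
        t0 = time.monotonic()
        manifest.timestamps[name] = time.time()
        try:
            manifest.stage_rows[name] = fn()
        except Exception as exc:
            manifest.status = f"failed at stage {name}: {exc}"
            manifest.write(out_dir / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.stage_seconds[name] = round(time.monotonic() - t0, 3)
        log.info("stage %s done in %.1fs", name, manifest.stage_seconds[name])
    manifest.status = "ok"
    manifest.write(out_dir / "manifest.json")
    return manifest
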