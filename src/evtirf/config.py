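"""Validated configuration types for the simulation/analysis pipeline.

All domain parameters live here: optical/camera settings (:class:`ImagingConfig`),
the antibody panel (:class:`MarkerPanel`), per-well experimental designs
(:class:`WellCondition`), spot-detection knobs (:class:`DetectionParams`), and the
end-to-end run description (:class:`RunConfig`, parsed from YAML).
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Number of stain channels / phenotype bits.
N_CHANNELS = 4
#: Number of nonzero phenotype classes for a 4-marker panel.
N_POPULATIONS = 2**N_CHANNELS - 1


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class ImagingConfig(_Frozen):
    """Optical and camera parameters of one simulated TIRFM field.

    The field is square with area ``field_area_um2``; only surface-immobilized
    vesicles within the ~200 nm evanescent excitation depth are imaged, so every
    emitter is rendered in focus. Intensities are in arbitrary camera units.
    """

    field_area_um2: float = 4356.0
    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.15
    background_mean: float = 100.0
    background_sd: float = 10.0
    photon_noise: bool = False
    evanescent_depth_nm: float = 200.0
    channel_names: tuple[str, str, str, str] = ("405", "488", "561", "640")
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ImagingConfig":
        if self.field_area_um2 <= 0:
            raise ValueError("field_area_um2 must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.psf_sigma_um < self.pixel_size_um:
            raise ValueError(
                "psf_sigma_um must be >= pixel_size_um (spots must span >1 pixel)"
            )
        if self.side_px < 64:
            raise ValueError(f"field side is {self.side_px} px; must be >= 64")
        return self

    @property
    def side_um(self) -> float:
        return math.sqrt(self.field_area_um2)

    @property
    def side_px(self) -> int:
        return int(round(self.side_um / self.pixel_size_um))

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um


class MarkerPanel(_Frozen):
    """Capture antibody plus the four-stain channel assignment.

    ``stain_markers`` are ordered by excitation channel; phenotype bit ``i``
    (value ``1 << i``) corresponds to ``stain_markers[i]``. The capture
    (immobilization) marker is metadata, not a phenotype bit, and may also
    appear in the stain panel (e.g. staining CD63 while capturing on CD63).
    """

    immobilization_marker: str = "CD81"
    stain_markers: tuple[str, str, str, str] = ("CD63", "HSP70", "TSG101", "ANXA5")

    @field_validator("stain_markers")
    @classmethod
    def _unique(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(set(v)) != len(v):
            raise ValueError("stain marker names must be unique")
        return v

    def bit_of(self, marker: str) -> int:
        """Bit value (1, 2, 4 or 8) of a stain marker."""
        try:
            return 1 << self.stain_markers.index(marker)
        except ValueError:
            raise KeyError(f"marker {marker!r} not in stain panel {self.stain_markers}")

    def label(self, bitmask: int) -> str:
        """Canonical phenotype label, suffix order = panel order, e.g. 'CD63+ANXA5+'."""
        if not 1 <= bitmask <= 2 ** len(self.stain_markers) - 1:
            raise ValueError(f"bitmask {bitmask} out of range for panel")
        return "".join(
            f"{m}+" for i, m in enumerate(self.stain_markers) if bitmask & (1 << i)
        )


#: Stain panel used for the GW4869 treatment comparison (CD63 capture).
GW4869_PANEL = MarkerPanel(
    immobilization_marker="CD63", stain_markers=("CD81", "STAM1", "TSG101", "ANXA5")
)


def default_composition() -> tuple[float, ...]:
    """Default 15-class phenotype mixture, in canonical population order.

    Weighted by marker count so the quadruple-positive class is the single
    largest population, triple-positives next, and single-positives rarest —
    the qualitative ranking seen for single-cell-secreted EVs.
    """
    # canonical order: popcount desc, then bitmask desc (see classification.enumerate_populations)
    weights = {4: 0.25, 3: 0.10, 2: 0.04, 1: 0.0275}
    masks = sorted(range(1, 16), key=lambda m: (-bin(m).count("1"), -m))
    comp = np.array([weights[bin(m).count("1")] for m in masks])
    return tuple(comp / comp.sum())


class WellCondition(_Frozen):
    """One experimental condition: cell occupancy, treatment, capture marker, rates.

    ``ev_rate`` is the expected number of true (cell-secreted) EVs per image;
    ``background_spot_rate`` the expected unspecific single-channel spots per
    image *per channel* (empty-well background adsorption). ``composition`` is
    the 15-class phenotype mixture in canonical population order.
    """

    label: str
    n_cells: int = 1  # 0, 1, 2 or 3 (3 means "3 or more")
    treatment: Literal["none", "GW4869"] = "none"
    immobilization_marker: str = "CD81"
    ev_rate: float = 1.6
    background_spot_rate: float = 0.2
    composition: tuple[float, ...] = Field(default_factory=default_composition)

    @model_validator(mode="after")
    def _check(self) -> "WellCondition":
        if self.n_cells not in (0, 1, 2, 3):
            raise ValueError("n_cells must be 0, 1, 2 or 3 (3 = '3 or more')")
        if self.ev_rate < 0:
            raise ValueError("ev_rate must be >= 0")
        if self.background_spot_rate < 0:
            raise ValueError("background_spot_rate must be >= 0")
        comp = np.asarray(self.composition, dtype=float)
        if comp.size != N_POPULATIONS:
            raise ValueError(
                f"composition must have {N_POPULATIONS} entries, got {comp.size}"
            )
        if np.any(comp < 0):
            raise ValueError("composition entries must be >= 0")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"composition must sum to 1 (got {comp.sum():.12g}) in condition {self.label!r}"
            )
        return self


def default_conditions() -> list["WellCondition"]:
    """Study-design defaults for the 0/1/2/3+ cell occupancy classes.

    Background adsorption rate 0.2/channel/image makes ~45% of empty-well
    images signal-free; the total signal rate for single-cell wells is three
    times the empty-well rate, and scales further with occupancy.
    """
    return [
        WellCondition(label="0cell", n_cells=0, ev_rate=0.0),
        WellCondition(label="1cell", n_cells=1, ev_rate=1.6),
        WellCondition(label="2cell", n_cells=2, ev_rate=3.2),
        WellCondition(label="3cell", n_cells=3, ev_rate=4.8),
    ]


class DetectionParams(_Frozen):
    """Knobs of the LoG blob detector.

    ``k_threshold`` is the detection threshold in units of the robust background
    SD of the filtered image above its robust mean — the single sensitivity knob.
    """

    log_sigma_px: float = 1.5
    k_threshold: float = 5.0
    min_separation_px: int = 2
    abs_floor: float = 1.0  # fallback threshold when the background SD is 0

    @model_validator(mode="after")
    def _check(self) -> "DetectionParams":
        if self.log_sigma_px <= 0:
            raise ValueError("log_sigma_px must be > 0")
        if self.k_threshold <= 0:
            raise ValueError("k_threshold must be > 0")
        if self.min_separation_px < 1:
            raise ValueError("min_separation_px must be >= 1")
        return self


class ConditionDesign(_Frozen):
    condition: WellCondition
    n_images: int

    @field_validator("n_images")
    @classmethod
    def _pos(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_images must be >= 1")
        return v


class Comparison(_Frozen):
    """A planned two-sample comparison between condition labels."""

    name: str
    a: str
    b: str
    tests: tuple[str, ...] = ("ks_bootstrap", "density_permutation", "median_fold")


class RunConfig(_Frozen):
    """Full description of one reproducible pipeline run."""

    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    panel: MarkerPanel = Field(default_factory=MarkerPanel)
    detection: DetectionParams = Field(default_factory=DetectionParams)
    colocalization_radius_um: float = 0.2
    snr: float = 10.0
    conditions: tuple[ConditionDesign, ...]
    comparisons: tuple[Comparison, ...] = ()
    n_resamples: int = 10000
    seed: int  # explicit; never wall-clock seeded

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.colocalization_radius_um <= 0:
            raise ValueError("colocalization_radius_um must be > 0")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        labels = [d.condition.label for d in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        for cmp_ in self.comparisons:
            for side in (cmp_.a, cmp_.b):
                if side not in labels:
                    raise ValueError(
                        f"comparison {cmp_.name!r} references undefined condition {side!r}"
                    )
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(text: str) -> RunConfig:
    """Parse YAML text into a validated :class:`RunConfig`.

    Pydantic reports precise field paths for every violation; defaults are
    injected for omitted fields.
    """
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    return RunConfig.model_validate(raw)


def demo_config(seed: int = 0, n_images: int = 50) -> RunConfig:
    """Small end-to-end demo design: the four occupancy conditions at SNR 10."""
    return RunConfig(
        conditions=tuple(
            ConditionDesign(condition=c, n_images=n_images)
            for c in default_conditions()
        ),
        comparisons=(
            Comparison(name="1cell_vs_0cell", a="1cell", b="0cell"),
            Comparison(name="2cell_vs_1cell", a="2cell", b="1cell"),
            Comparison(name="3cell_vs_1cell", a="3cell", b="1cell"),
        ),
        n_resamples=2000,
        seed=seed,
    )


def _as_sequence(x: Sequence[float]) -> np.ndarray:
    return np.asarray(x, dtype=float)
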