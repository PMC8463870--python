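"""Ground-truthed synthetic four-channel TIRFM fields.

The forward model: each field is a square region of ``field_area_um2`` imaged
through the evanescent excitation layer, so every vesicle is a surface-bound,
in-focus point emitter. A true EV carries a nonzero 4-bit phenotype and renders
as a 2-D Gaussian spot (the PSF) in every channel whose bit is set; unspecific
background adsorption produces additional single-channel false spots. Per-image
counts are Poisson; spot brightnesses are log-normal, independent across
channels by default (an optional log-space correlation enables positive-control
tests of the channel-correlation analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import N_CHANNELS, N_POPULATIONS, ImagingConfig, MarkerPanel, WellCondition
from .seeding import substream

#: Default log-normal brightness spread (SD of log amplitude).
SIGMA_LOG = 0.35


@dataclass(frozen=True)
class TrueEV:
    x_um: float
    y_um: float
    bitmask: int  # 1..15
    amplitudes: tuple[float, ...]  # length 4; NaN where the bit is unset


@dataclass(frozen=True)
class FalseSpot:
    x_um: float
    y_um: float
    channel: int
    amplitude: float


@dataclass
class GroundTruth:
    """All emitters of one field: true EVs plus per-channel false spots."""

    evs: list[TrueEV] = field(default_factory=list)
    false_spots: list[FalseSpot] = field(default_factory=list)

    @property
    def n_signals(self) -> int:
        """Total countable signals: each EV and each false spot is one."""
        return len(self.evs) + len(self.false_spots)

    def to_frame(self, image_id: str = "") -> pd.DataFrame:
        rows = []
        for ev in self.evs:
            rows.append(
                dict(
                    image_id=image_id,
                    x_um=ev.x_um,
                    y_um=ev.y_um,
                    bitmask=ev.bitmask,
                    is_background=False,
                    **{f"amp_ch{i}": ev.amplitudes[i] for i in range(N_CHANNELS)},
                )
            )
        for sp in self.false_spots:
            amps = [np.nan] * N_CHANNELS
            amps[sp.channel] = sp.amplitude
            rows.append(
                dict(
                    image_id=image_id,
                    x_um=sp.x_um,
                    y_um=sp.y_um,
                    bitmask=1 << sp.channel,
                    is_background=True,
                    **{f"amp_ch{i}": amps[i] for i in range(N_CHANNELS)},
                )
            )
        cols = ["image_id", "x_um", "y_um", "bitmask", "is_background"] + [
            f"amp_ch{i}" for i in range(N_CHANNELS)
        ]
        return pd.DataFrame(rows, columns=cols)


def canonical_masks() -> np.ndarray:
    """The 15 nonzero bitmasks in canonical population order."""
    return np.array(sorted(range(1, 16), key=lambda m: (-bin(m).count("1"), -m)))


def sample_phenotypes(
    composition: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. nonzero phenotype bitmasks from a 15-class mixture.

    ``composition`` is indexed in canonical population order (marker count
    descending, then bitmask descending).
    """
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (N_POPULATIONS,):
        raise ValueError(f"composition must have {N_POPULATIONS} entries")
    if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be nonnegative and sum to 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.array([], dtype=int)
    idx = rng.choice(N_POPULATIONS, size=n, p=comp / comp.sum())
    return canonical_masks()[idx]


def sample_amplitudes(
    n: int,
    rng: np.random.Generator,
    snr: float = 10.0,
    background_sd: float = 10.0,
    sigma_log: float = SIGMA_LOG,
    channel_rho: float = 0.0,
) -> np.ndarray:
    """Log-normal per-channel peak amplitudes, median ``snr * background_sd``.

    ``channel_rho`` is the pairwise correlation of log-amplitudes across
    channels (0 = independent; >0 is the positive control for the Pearson
    channel-correlation analysis).
    """
    median = snr * background_sd
    if channel_rho == 0.0:
        z = rng.standard_normal((n, N_CHANNELS))
    else:
        cov = np.full((N_CHANNELS, N_CHANNELS), channel_rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(N_CHANNELS), cov, size=n)
    return median * np.exp(sigma_log * z)


def sample_ground_truth(
    condition: WellCondition,
    config: ImagingConfig,
    rng: np.random.Generator,
    snr: float = 10.0,
    sigma_log: float = SIGMA_LOG,
    channel_rho: float = 0.0,
) -> GroundTruth:
    """Sample one field's emitters for a well condition.

    True-EV count ~ Poisson(ev_rate); false spots per channel ~
    Poisson(background_spot_rate); positions uniform in the field.
    """
    side = config.side_um
    truth = GroundTruth()

    n_ev = rng.poisson(condition.ev_rate)
    masks = sample_phenotypes(condition.composition, n_ev, rng)
    pos = rng.uniform(0.0, side, size=(n_ev, 2))
    amps = sample_amplitudes(
        n_ev, rng, snr=snr, background_sd=config.background_sd,
        sigma_log=sigma_log, channel_rho=channel_rho,
    )
    for i in range(n_ev):
        a = tuple(
            float(amps[i, c]) if masks[i] & (1 << c) else float("nan")
            for c in range(N_CHANNELS)
        )
        truth.evs.append(TrueEV(float(pos[i, 0]), float(pos[i, 1]), int(masks[i]), a))

    for c in range(N_CHANNELS):
        n_bg = rng.poisson(condition.background_spot_rate)
        bpos = rng.uniform(0.0, side, size=(n_bg, 2))
        bamp = sample_amplitudes(
            n_bg, rng, snr=snr, background_sd=config.background_sd, sigma_log=sigma_log
        )
        for j in range(n_bg):
            truth.false_spots.append(
                FalseSpot(float(bpos[j, 0]), float(bpos[j, 1]), c, float(bamp[j, c]))
            )
    return truth


def _add_spot(
    img: np.ndarray, x_px: float, y_px: float, amplitude: float, sigma_px: float
) -> None:
    """Accumulate a Gaussian spot into ``img`` over a +/-5 sigma patch."""
    n = img.shape[0]
    half = int(np.ceil(5 * sigma_px))
    r0, r1 = max(0, int(y_px) - half), min(n, int(y_px) + half + 1)
    c0, c1 = max(0, int(x_px) - half), min(n, int(x_px) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None]
    cc = np.arange(c0, c1)[None, :]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - y_px) ** 2 + (cc - x_px) ** 2) / (2.0 * sigma_px**2)
    )


def render_field(
    truth: GroundTruth,
    config: ImagingConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a (4, H, W) float field from ground truth.

    Each channel is ``background_mean`` plus the Gaussian spots of the emitters
    lit in that channel, then optional Poisson shot noise on the expected
    signal and additive Gaussian read noise; pixel values are clipped at 0.
    """
    side_px = config.side_px
    sigma_px = config.psf_sigma_px
    clean = np.full((N_CHANNELS, side_px, side_px), config.background_mean, dtype=float)

    def check(x: float, y: float) -> None:
        if not (0 <= x <= config.side_um and 0 <= y <= config.side_um):
            raise ValueError(f"emitter position ({x}, {y}) um outside field")

    for ev in truth.evs:
        check(ev.x_um, ev.y_um)
        if ev.bitmask == 0:
            raise ValueError("true EV with zero bitmask")
        for c in range(N_CHANNELS):
            if ev.bitmask & (1 << c):
                _add_spot(
                    clean[c],
                    ev.x_um / config.pixel_size_um,
                    ev.y_um / config.pixel_size_um,
                    ev.amplitudes[c],
                    sigma_px,
                )
    for sp in truth.false_spots:
        check(sp.x_um, sp.y_um)
        _add_spot(
            clean[sp.channel],
            sp.x_um / config.pixel_size_um,
            sp.y_um / config.pixel_size_um,
            sp.amplitude,
            sigma_px,
        )

    img = clean
    if rng is not None:
        if config.photon_noise:
            img = rng.poisson(np.clip(clean, 0, None)).astype(float)
        if config.background_sd > 0:
            img = img + rng.normal(0.0, config.background_sd, size=clean.shape)
    return np.clip(img, 0.0, None)


def render_channel(
    truth: GroundTruth,
    config: ImagingConfig,
    rng: Optional[np.random.Generator] = None,
    channel: int = 0,
) -> np.ndarray:
    """Render a single channel (H, W); same forward model as :func:`render_field`."""
    side_px = config.side_px
    sigma_px = config.psf_sigma_px
    clean = np.full((side_px, side_px), config.background_mean, dtype=float)
    for ev in truth.evs:
        if ev.bitmask & (1 << channel):
            _add_spot(clean, ev.x_um / config.pixel_size_um,
                      ev.y_um / config.pixel_size_um, ev.amplitudes[channel], sigma_px)
    for sp in truth.false_spots:
        if sp.channel == channel:
            _add_spot(clean, sp.x_um / config.pixel_size_um,
                      sp.y_um / config.pixel_size_um, sp.amplitude, sigma_px)
    img = clean
    if rng is not None:
        if config.photon_noise:
            img = rng.poisson(np.clip(clean, 0, None)).astype(float)
        if config.background_sd > 0:
            img = img + rng.normal(0.0, config.background_sd, size=clean.shape)
    return np.clip(img, 0.0, None)


def simulate_spot_field(
    n_spots: int,
    config: ImagingConfig,
    rng: np.random.Generator,
    snr: float = 10.0,
    margin_um: float = 1.0,
    sigma_log: float = SIGMA_LOG,
) -> tuple[GroundTruth, np.ndarray]:
    """One single-channel field with exactly ``n_spots`` emitters.

    Convenience for detector benchmarking: positions are uniform inside the
    field with a margin (so truth spots are not border-rejected), brightnesses
    log-normal at the given SNR. Returns (truth, channel-0 image).
    """
    pos = rng.uniform(margin_um, config.side_um - margin_um, size=(n_spots, 2))
    amps = sample_amplitudes(n_spots, rng, snr=snr,
                             background_sd=config.background_sd, sigma_log=sigma_log)
    truth = GroundTruth(
        evs=[
            TrueEV(float(pos[i, 0]), float(pos[i, 1]), 1,
                   (float(amps[i, 0]), float("nan"), float("nan"), float("nan")))
            for i in range(n_spots)
        ]
    )
    return truth, render_channel(truth, config, rng, channel=0)


@dataclass
class SimulatedExperiment:
    """In-memory result of :func:`generate_experiment`."""

    images: dict[str, np.ndarray]  # image_id -> (4, H, W) float
    truths: dict[str, GroundTruth]
    metadata: pd.DataFrame  # image_id, well_id, n_cells, treatment, immobilization_marker, condition
    panel: MarkerPanel
    config: ImagingConfig

    def truth_frame(self) -> pd.DataFrame:
        frames = [t.to_frame(iid) for iid, t in self.truths.items()]
        frames = [f for f in frames if len(f)]
        if not frames:
            return GroundTruth().to_frame()
        return pd.concat(frames, ignore_index=True)


def generate_experiment(
    conditions: Sequence[tuple[WellCondition, int]],
    panel: MarkerPanel,
    config: ImagingConfig,
    seed: int,
    snr: float = 10.0,
    sigma_log: float = SIGMA_LOG,
    channel_rho: float = 0.0,
    render: bool = True,
) -> SimulatedExperiment:
    """Simulate a full multi-condition experiment, reproducibly from ``seed``.

    One metadata row per image; image ids are ``<condition>_<index>``. With
    ``render=False`` only ground truths are produced (fast counts-level use).
    """
    images: dict[str, np.ndarray] = {}
    truths: dict[str, GroundTruth] = {}
    meta_rows = []
    for cond, n_images in conditions:
        if n_images < 1:
            raise ValueError(f"n_images must be >= 1 for condition {cond.label!r}")
        for i in range(n_images):
            image_id = f"{cond.label}_{i:05d}"
            rng = substream(seed, "simulate", image_id)
            truth = sample_ground_truth(
                cond, config, rng, snr=snr, sigma_log=sigma_log, channel_rho=channel_rho
            )
            truths[image_id] = truth
            if render:
                images[image_id] = render_field(truth, config, rng)
            meta_rows.append(
                dict(
                    image_id=image_id,
                    well_id=image_id,
                    n_cells=cond.n_cells,
                    treatment=cond.treatment,
                    immobilization_marker=cond.immobilization_marker,
                    condition=cond.label,
                )
            )
    metadata = pd.DataFrame(
        meta_rows,
        columns=[
            "image_id",
            "well_id",
            "n_cells",
            "treatment",
            "immobilization_marker",
            "condition",
        ],
    )
    return SimulatedExperiment(
        images=images, truths=truths, metadata=metadata, panel=panel, config=config
    )
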