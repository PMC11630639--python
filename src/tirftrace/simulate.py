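"""Virtual two-color TIRF movies with known ground truth.

The generator emulates the stochastic structure the analysis assumes:
sparse immobilized multi-subunit "green" (Venus-tagged) spots that bleach
stepwise, per-subunit "red" (rhodamine-calmodulin) binding/unbinding
sampled from an exact continuous-time Markov chain, green-to-red spectral
leakage, a decaying autofluorescent background, uneven illumination, and
EMCCD noise (Poisson photons -> Gamma gain register -> Gaussian read noise).

Binding is per-subunit independent with identical rates; a bound ligand
whose fluorophore photobleaches still occupies its subunit (invisibly)
until it dissociates, after which the site can rebind a fresh, almost
surely unbleached, ligand from solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import MovieStack
from .spots import Trace

__all__ = [
    "SimConfig",
    "OccupancyTrajectory",
    "simulate_binding_trajectory",
    "simulate_bleach_staircase",
    "place_spots",
    "render_movie",
    "simulate_field",
    "write_simulation",
]


@dataclass
class SimConfig:
    """Virtual-movie parameters.

    Intensity units are ADU; the single-fluorophore per-frame intensity is
    ``step_mean`` ADU, i.e. ``step_mean / emccd_gain`` detected photons.
    ``n_frames`` counts recorded camera frames; after deinterleaving each
    logical channel has ``n_frames // 2`` frames at twice the interval.
    """

    field_size_px: tuple = (512, 512)
    pixel_nm: float = 100.0
    frame_interval_s: float = 0.1
    n_frames: int = 500
    psf_sigma_nm: float = 74.0
    n_spots: int = 50
    subunit_count: int = 14
    cam_conc: float = 30e-9          # M
    kon_per_M_s: float = 1e6
    koff_s: float = 0.5
    kpb_green_s: float = 0.04
    kpb_red_s: float = 0.1
    dark_fraction: float = 0.2
    step_mean: float = 3000.0        # ADU per fluorophore per frame
    step_sd: float = 450.0
    leak_fraction: float = 0.10
    fret_per_bound: float = 0.0      # optional FRET ADU per bound ligand
    bg_amp1: float = 6.0             # photons / pixel / frame
    bg_k1: float = 0.2
    bg_amp2: float = 3.0
    bg_k2: float = 0.02
    bg_offset: float = 2.0
    emccd_gain: float = 30.0
    read_noise: float = 10.0         # ADU
    camera_baseline: float = 100.0   # ADU
    min_separation_px: float = 20.0  # 2 um at 100 nm/px
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.kon_per_M_s, self.koff_s, self.kpb_green_s, self.kpb_red_s)
        if any((not np.isfinite(r)) or r < 0 for r in rates):
            raise ValueError("rates must be finite and nonnegative")
        if not 0 <= self.leak_fraction < 1:
            raise ValueError("leak_fraction must be in [0, 1)")
        if not 0 <= self.dark_fraction < 1:
            raise ValueError("dark_fraction must be in [0, 1)")
        if self.subunit_count < 1:
            raise ValueError("subunit_count must be >= 1")
        if self.cam_conc < 0:
            raise ValueError("cam_conc must be >= 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_nm

    @property
    def channel_frames(self) -> int:
        return self.n_frames // 2

    @property
    def channel_interval_s(self) -> float:
        return 2 * self.frame_interval_s


@dataclass
class OccupancyTrajectory:
    """Ground-truth visible ligand occupancy for one spot.

    ``events`` holds (time_s, delta, cause) with cause in
    {"bind", "unbind", "photobleach"}; photobleach events only decrement.
    """

    times: np.ndarray
    n_bound: np.ndarray
    events: List[tuple] = field(default_factory=list)
    subunit_count: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_bound = np.asarray(self.n_bound, dtype=int)
        if np.any(self.n_bound < 0) or np.any(self.n_bound > self.subunit_count):
            raise ValueError("occupancy must stay within [0, S]")


def simulate_binding_trajectory(
    S: int,
    cam_conc: float,
    kon: float,
    koff: float,
    kpb_red: float,
    duration: float,
    seed,
    dt: float = 0.2,
) -> OccupancyTrajectory:
    """Exact Gillespie simulation of per-subunit ligand exchange.

    The initial state is drawn from the stationary law in the dark
    (Binomial(S, kon*C / (kon*C + koff)), all fluorophores bright);
    photobleaching (hazard ``kpb_red`` per bright fluorophore) applies only
    for t >= 0, when the laser is on.  The trajectory is sampled onto the
    frame grid ``0, dt, 2*dt, ...`` (value at the frame start).
    """
    for name, v in (("kon", kon), ("koff", koff), ("kpb_red", kpb_red),
                    ("cam_conc", cam_conc)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    kon_c = kon * cam_conc
    p = kon_c / (kon_c + koff) if (kon_c + koff) > 0 else 0.0
    n_bright = int(rng.binomial(S, p))
    n_dark = 0  # bound but photobleached

    grid = np.arange(0.0, duration + 1e-12, dt)
    sampled = np.empty(len(grid), dtype=int)
    events: List[tuple] = []
    t = 0.0
    gi = 0
    while True:
        n_free = S - n_bright - n_dark
        r_bind = n_free * kon_c
        r_unb_b = n_bright * koff
        r_unb_d = n_dark * koff
        r_pb = n_bright * kpb_red
        total = r_bind + r_unb_b + r_unb_d + r_pb
        t_next = t + (rng.exponential(1.0 / total) if total > 0 else np.inf)
        while gi < len(grid) and grid[gi] < t_next - 1e-12:
            sampled[gi] = n_bright
            gi += 1
        if gi >= len(grid) or t_next > duration:
            break
        t = t_next
        u = rng.uniform(0, total)
        if u < r_bind:
            n_bright += 1
            events.append((t, +1, "bind"))
        elif u < r_bind + r_unb_b:
            n_bright -= 1
            events.append((t, -1, "unbind"))
        elif u < r_bind + r_unb_b + r_unb_d:
            n_dark -= 1  # invisible: dark-bound ligand leaves
        else:
            n_bright -= 1
            n_dark += 1
            events.append((t, -1, "photobleach"))
    return OccupancyTrajectory(grid, sampled, events, subunit_count=S)


def simulate_bleach_staircase(
    n_fluor: int,
    kpb: float,
    step_mean: float,
    step_sd: float,
    noise_sd: float,
    duration: float,
    dt: float,
    seed,
    dark_fraction: float = 0.0,
) -> Trace:
    """A photobleaching staircase trace for one multi-fluorophore spot.

    Each fluorophore has an amplitude drawn from the single-fluorophore
    intensity distribution N(step_mean, step_sd) (clipped at 0) and bleaches
    once at an exponential time with hazard ``kpb``; ``dark_fraction``
    removes fluorophores before t = 0.  White Gaussian noise of SD
    ``noise_sd`` is added per frame.
    """
    if n_fluor < 0:
        raise ValueError("n_fluor must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration, dt)
    signal = np.zeros(len(times))
    if n_fluor:
        amps = np.clip(rng.normal(step_mean, step_sd, size=n_fluor), 0.0, None)
        lit = rng.uniform(size=n_fluor) >= dark_fraction
        if kpb > 0:
            bleach_t = rng.exponential(1.0 / kpb, size=n_fluor)
        else:
            bleach_t = np.full(n_fluor, np.inf)
        for a, on, tb in zip(amps, lit, bleach_t):
            if on:
                signal += a * (times < tb)
    noise = rng.normal(0.0, noise_sd, size=len(times)) if noise_sd > 0 else 0.0
    return Trace(spot_id=0, times=times, intensity=signal + noise,
                 channel_tag="venus")


def place_spots(
    field_size: tuple, n_spots: int, min_separation_px: float, rng, margin: int = 8
) -> np.ndarray:
    """Uniform spot centers with rejection-sampled minimum separation."""
    centers = []
    attempts = 0
    max_attempts = 200 * max(n_spots, 1)
    while len(centers) < n_spots and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(margin, field_size[0] - margin)
        c = rng.uniform(margin, field_size[1] - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_separation_px**2
               for rr, cc in centers):
            centers.append((r, c))
    if len(centers) < n_spots:
        raise ValueError("could not place spots at requested density/separation")
    return np.array(centers)


def default_illum_profile(field_size: tuple) -> np.ndarray:
    """Smooth multiplicative vignette: 1 at center, ~0.7 at the corners."""
    rr = np.arange(field_size[0])[:, None] - (field_size[0] - 1) / 2
    cc = np.arange(field_size[1])[None, :] - (field_size[1] - 1) / 2
    r2 = (rr**2 + cc**2) / ((field_size[0] / 2) ** 2 + (field_size[1] / 2) ** 2)
    return 1.0 - 0.3 * r2


def _psf_patch(center: tuple, sigma_px: float, field_size: tuple, radius: int = 5):
    """Unit-mass Gaussian PSF patch and its field slices (edge-clipped)."""
    r0, c0 = center
    ri = int(round(r0))
    ci = int(round(c0))
    lo_r = max(ri - radius, 0)
    hi_r = min(ri + radius + 1, field_size[0])
    lo_c = max(ci - radius, 0)
    hi_c = min(ci + radius + 1, field_size[1])
    rows = np.arange(lo_r, hi_r)[:, None]
    cols = np.arange(lo_c, hi_c)[None, :]
    patch = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma_px**2))
    patch /= 2 * np.pi * sigma_px**2  # unit total mass on the infinite plane
    return patch, (slice(lo_r, hi_r), slice(lo_c, hi_c))


def render_projection(
    field_size: tuple,
    centers: np.ndarray,
    amps_adu: np.ndarray,
    psf_sigma_px: float,
    rng,
    bg_adu: float = 300.0,
    noise_sd_adu: float = 40.0,
    illum_profile: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Time-averaged projected image of a spot field.

    Shortcut for colocalization studies: renders what the temporal mean of
    a movie looks like (PSF spots on an uneven background, with the
    shot/read noise already averaged down to ``noise_sd_adu`` per pixel)
    without simulating every frame.
    """
    if illum_profile is None:
        illum_profile = default_illum_profile(field_size)
    img = bg_adu * illum_profile.copy()
    for (r, c), a in zip(centers, amps_adu):
        patch, sl = _psf_patch((r, c), psf_sigma_px, field_size)
        img[sl] += a * patch * illum_profile[sl]
    return img + rng.normal(0.0, noise_sd_adu, field_size)


@dataclass
class GroundTruthSpot:
    spot_id: int
    center_px: tuple
    venus_adu: np.ndarray       # per channel frame
    red_adu: np.ndarray         # per channel frame
    occupancy: Optional[OccupancyTrajectory] = None
    s_true: int = 0             # lit Venus fluorophores at t=0
    too_close: bool = False


def _emccd(rng, photons: np.ndarray, gain: float, read_noise: float,
           baseline: float) -> np.ndarray:
    """Photon image -> 16-bit camera counts.

    Poisson photoelectrons, Gamma-distributed EM register output (shape = n,
    scale = gain), Gaussian read noise, fixed baseline offset.
    """
    n = rng.poisson(np.clip(photons, 0, None))
    amplified = rng.standard_gamma(n) * gain  # standard_gamma(0) == 0
    out = amplified + rng.normal(0.0, read_noise, size=photons.shape) + baseline
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def render_movie(
    config: SimConfig,
    truth_spots: Sequence[GroundTruthSpot],
    rng=None,
    illum_profile: Optional[np.ndarray] = None,
) -> tuple:
    """Render the interleaved two-camera recording for given ground truth.

    Even recorded frames (0-based) are blue-excited: the green camera sees
    the Venus signal, the red camera a mixed signal (leakage x Venus + FRET).
    Odd frames are olive-excited: the red camera sees rhodamine, the green
    camera is blank.  Background follows the dual-exponential decay times
    the illumination profile on blue-excited frames.

    Returns ``(green_cam, red_cam)`` MovieStacks of uint16-quantized counts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.field_size_px
    sigma = config.psf_sigma_px
    if illum_profile is None:
        illum_profile = default_illum_profile(fs)

    for spot in truth_spots:
        for other in truth_spots:
            if other.spot_id >= spot.spot_id:
                continue
            d2 = ((spot.center_px[0] - other.center_px[0]) ** 2
                  + (spot.center_px[1] - other.center_px[1]) ** 2)
            if d2 < config.min_separation_px**2:
                spot.too_close = True
                import warnings

                warnings.warn(
                    f"spots {spot.spot_id} and {other.spot_id} closer than "
                    f"{config.min_separation_px} px", stacklevel=2,
                )

    patches = [
        _psf_patch(s.center_px, sigma, fs) for s in truth_spots
    ]
    gain = config.emccd_gain
    green = np.empty((config.n_frames, *fs), dtype=np.uint16)
    red = np.empty((config.n_frames, *fs), dtype=np.uint16)

    for j in range(config.n_frames):
        i = j // 2  # channel frame index
        t = j * config.frame_interval_s
        blue = j % 2 == 0
        if blue:
            bg = (config.bg_amp1 * np.exp(-config.bg_k1 * t)
                  + config.bg_amp2 * np.exp(-config.bg_k2 * t)
                  + config.bg_offset)
            g_photons = bg * illum_profile
            r_photons = 0.3 * bg * illum_profile  # weaker bleed of bg into red
            g_photons = g_photons.copy()
            r_photons = r_photons.copy()
            for spot, (patch, sl) in zip(truth_spots, patches):
                v = spot.venus_adu[i] if i < len(spot.venus_adu) else 0.0
                local = illum_profile[sl]
                g_photons[sl] += (v / gain) * patch * local
                nb = 0
                if spot.occupancy is not None and i < len(spot.occupancy.n_bound):
                    nb = spot.occupancy.n_bound[i]
                mixed_adu = config.leak_fraction * v + config.fret_per_bound * nb
                r_photons[sl] += (mixed_adu / gain) * patch * local
            green[j] = _emccd(rng, g_photons, gain, config.read_noise,
                              config.camera_baseline)
            red[j] = _emccd(rng, r_photons, gain, config.read_noise,
                            config.camera_baseline)
        else:
            g_photons = np.full(fs, 0.1)  # blank channel: residual light only
            r_photons = (config.bg_offset * 0.5) * illum_profile
            r_photons = r_photons.copy()
            for spot, (patch, sl) in zip(truth_spots, patches):
                radu = spot.red_adu[i] if i < len(spot.red_adu) else 0.0
                r_photons[sl] += (radu / gain) * patch * illum_profile[sl]
            green[j] = _emccd(rng, g_photons, gain, config.read_noise,
                              config.camera_baseline)
            red[j] = _emccd(rng, r_photons, gain, config.read_noise,
                            config.camera_baseline)

    return (
        MovieStack(green, config.frame_interval_s, "green_cam"),
        MovieStack(red, config.frame_interval_s, "red_cam"),
    )


def simulate_field(config: SimConfig, rng=None) -> tuple:
    """Build ground truth for a whole field and render it.

    Returns ``(green_cam, red_cam, truth_spots)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    centers = place_spots(config.field_size_px, config.n_spots,
                          config.min_separation_px, rng)
    nchan = config.channel_frames
    dt = config.channel_interval_s
    duration = nchan * dt
    truth: List[GroundTruthSpot] = []
    for sid, (r, c) in enumerate(centers):
        # Venus staircase for this spot's subunits
        stair = simulate_bleach_staircase(
            config.subunit_count, config.kpb_green_s, config.step_mean,
            config.step_sd, 0.0, duration, dt,
            seed=rng.integers(0, 2**31 - 1), dark_fraction=config.dark_fraction,
        )
        s_true = int(round(stair.intensity[0] / config.step_mean)) if config.step_mean else 0
        occ = simulate_binding_trajectory(
            config.subunit_count, config.cam_conc, config.kon_per_M_s,
            config.koff_s, config.kpb_red_s, duration,
            seed=rng.integers(0, 2**31 - 1), dt=dt,
        )
        red_adu = config.step_mean * occ.n_bound[:nchan].astype(float)
        truth.append(GroundTruthSpot(
            spot_id=sid, center_px=(float(r), float(c)),
            venus_adu=stair.intensity, red_adu=red_adu,
            occupancy=occ, s_true=s_true,
        ))
    green, red = render_movie(config, truth, rng=rng)
    return green, red, truth


def write_simulation(outdir, config: SimConfig, green: MovieStack,
                     red: MovieStack, truth_spots: Sequence[GroundTruthSpot]) -> None:
    """Write TIFF stacks, a JSON config sidecar, and ground-truth CSVs."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "green_cam.tif",
                     green.frames.astype(np.uint16), photometric="minisblack")
    tifffile.imwrite(outdir / "red_cam.tif",
                     red.frames.astype(np.uint16), photometric="minisblack")
    cfg = asdict(config)
    cfg["field_size_px"] = list(cfg["field_size_px"])
    (outdir / "sim_config.json").write_text(json.dumps(cfg, indent=2))
    rows = []
    for s in truth_spots:
        if s.occupancy is not None:
            for t, d, cause in s.occupancy.events:
                rows.append((s.spot_id, t, d, cause))
    pd.DataFrame(rows, columns=["spot_id", "time_s", "delta", "cause"]).to_csv(
        outdir / "events.csv", index=False
    )
    pd.DataFrame(
        {
            "spot_id": [s.spot_id for s in truth_spots],
            "row": [s.center_px[0] for s in truth_spots],
            "col": [s.center_px[1] for s in truth_spots],
            "s_true": [s.s_true for s in truth_spots],
            "n_cam_initial": [
                int(s.occupancy.n_bound[0]) if s.occupancy is not None else 0
                for s in truth_spots
            ],
        }
    ).to_csv(outdir / "truth_spots.csv", index=False)
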