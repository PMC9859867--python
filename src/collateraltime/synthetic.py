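"""Seeded digital contrast-enhancement phantoms for dynamic CT collateral scoring.

The phantom emulates the imaging situation the pipeline is built for: a
~30-frame CT perfusion (CTP) acquisition at ~2 s intervals over ~55-60 s,
plus three multiphase CTA (mCTA) volumes sampled from the same enhancement
model at bolus-tracked times with ~8 s inter-acquisition delays.

Model
-----
Each hemisphere carries a mirrored tree of tubular vessels inside a
brain-shaped ellipsoid. Arterial enhancement above the unenhanced blood
baseline follows a gamma-variate bolus curve plus a slowly rising shared
recirculation term (the blood-pool equilibrium that makes the arteriovenous
ratio return toward 1 late in the acquisition). The venous curve is the
arterial curve delayed by the arteriovenous transit time, with a small early
arterial admixture, so the raw AV ratio is bounded near
``1 / venous_early_fraction`` (= 20 at the default 0.05). Vessels on the
occluded side follow the arterial curve scaled by ``collateral_fraction``
and delayed by ``collateral_delay_s`` — delayed, attenuated retrograde
filling via leptomeningeal collaterals. Each vessel voxel carries a
deterministic amplitude factor (branch calibre times a radial
partial-volume falloff) so that enhanced vessel volume varies smoothly with
the segmentation threshold and with the collateral fraction.

Per-subject covariates emulate an early-ischemia score (ASPECTS-like, 0-10)
and a deficit score (NIHSS-like, 0-42) linearly linked to the collateral
fraction plus noise, so cohort association statistics have recoverable
structure.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .series import CTPSeries, RegionSpec, SphereROI

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "PhantomModel",
    "gamma_variate",
    "generate_phantom",
    "sample_mcta",
    "generate_cohort",
    "cohort_configs",
]


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Parameters of one synthetic subject.

    Times are seconds from the first CTP frame; intensities are HU.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 4.0)
    frame_interval_s: float = 2.0
    duration_s: float = 58.0
    aif_t0_s: float = 8.0            # arterial contrast arrival
    aif_alpha: float = 3.0           # gamma-variate shape
    aif_beta_s: float = 2.0          # gamma-variate scale -> peak at t0 + alpha*beta
    aif_amplitude_hu: float = 350.0  # peak arterial enhancement above blood baseline
    venous_delay_s: float = 6.5      # arteriovenous transit time
    venous_early_fraction: float = 0.05   # early arterial admixture in the venous ROI
    recirc_fraction: float = 0.25    # blood-pool equilibrium plateau / peak
    recirc_delay_s: float = 12.0     # recirculation onset after arrival
    recirc_tau_s: float = 12.0       # recirculation rise time constant
    collateral_fraction: float = 1.0
    collateral_delay_s: float = 0.0
    noise_sd_hu: float = 5.0
    baseline_hu: float = 40.0        # unenhanced (unclotted) blood
    tissue_hu: float = 30.0
    occlusion_side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in (self.frame_interval_s, self.duration_s,
                                self.aif_alpha, self.aif_beta_s,
                                self.venous_delay_s, self.recirc_tau_s)):
            raise ConfigurationError("all time constants and shape parameters must be positive")
        if self.n_frames < 20:
            raise ConfigurationError(
                f"duration/interval gives {self.n_frames} frames; at least 20 required"
            )
        if not 0.0 <= self.collateral_fraction <= 1.0:
            raise ConfigurationError("collateral_fraction must lie in [0, 1]")
        if not 0.0 <= self.venous_early_fraction < 1.0:
            raise ConfigurationError("venous_early_fraction must lie in [0, 1)")
        if self.collateral_delay_s < 0:
            raise ConfigurationError("collateral_delay_s must be non-negative")
        if self.occlusion_side not in ("left", "right"):
            raise ConfigurationError("occlusion_side must be 'left' or 'right'")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_s / self.frame_interval_s)) + 1

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    occlusion_side: str
    collateral_fraction: float
    true_arrival_s: float
    true_mcta_offset_s: float | None = None
    mcta_delays_s: tuple[float, float] | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        asp = self.covariates.get("aspects")
        nih = self.covariates.get("nihss")
        if asp is not None and not 0 <= asp <= 10:
            raise ConfigurationError("ASPECTS-like covariate out of range [0, 10]")
        if nih is not None and not 0 <= nih <= 42:
            raise ConfigurationError("NIHSS-like covariate out of range [0, 42]")


# ---------------------------------------------------------------------------
# bolus model
# ---------------------------------------------------------------------------

def gamma_variate(t, t0: float, alpha: float, beta: float, amplitude: float):
    """Normalized gamma-variate bolus curve.

    Zero before ``t0``; afterwards
    ``amplitude * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)``,
    which peaks at exactly ``amplitude`` when ``t = t0 + alpha*beta``.
    """
    if alpha <= 0 or beta <= 0:
        raise ConfigurationError("gamma-variate alpha and beta must be positive")
    t = np.asarray(t, dtype=float)
    tau = t - t0
    out = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    out[pos] = amplitude * (tp / (alpha * beta)) ** alpha * np.exp(alpha - tp / beta)
    return out if out.ndim else float(out)


def _recirculation(c: PhantomConfig, t):
    """Shared blood-pool equilibrium term: contrast recirculates and mixes,
    lifting both arterial and venous enhancement toward a common plateau."""
    t = np.asarray(t, dtype=float)
    tau = t - (c.aif_t0_s + c.recirc_delay_s)
    out = np.where(
        tau > 0,
        c.recirc_fraction * c.aif_amplitude_hu
        * (1.0 - np.exp(-np.clip(tau, 0, None) / c.recirc_tau_s)),
        0.0)
    return out if out.ndim else float(out)


def arterial_enhancement(c: PhantomConfig, t):
    bolus = gamma_variate(t, c.aif_t0_s, c.aif_alpha, c.aif_beta_s, c.aif_amplitude_hu)
    return bolus + _recirculation(c, t)


def venous_enhancement(c: PhantomConfig, t):
    """First-pass bolus delayed by the arteriovenous transit time, plus a
    small early arterial admixture and the shared recirculation term."""
    f = c.venous_early_fraction
    # the early admixture lags the artery slightly too, so the pre-transit
    # AV ratio is strictly decreasing rather than an exact plateau at 1/f
    early = gamma_variate(np.asarray(t, float) - 0.5,
                          c.aif_t0_s, c.aif_alpha, c.aif_beta_s, c.aif_amplitude_hu)
    late = gamma_variate(np.asarray(t, float) - c.venous_delay_s,
                         c.aif_t0_s, c.aif_alpha, c.aif_beta_s, c.aif_amplitude_hu)
    return f * early + (1.0 - f) * late + _recirculation(c, t)


def occluded_enhancement(c: PhantomConfig, t):
    """Collateral filling: the arterial curve scaled by the collateral
    fraction and delayed by the collateral transit time, averaged over a
    symmetric spread of route delays (supply arrives via several
    leptomeningeal paths of different lengths, which disperses and flattens
    the occluded-side bolus)."""
    t = np.asarray(t, float)
    spread = min(2.0, 0.8 * c.collateral_delay_s)
    offsets = np.linspace(-spread, spread, 7)
    bolus = 0.0
    recirc = 0.0
    for off in offsets:
        shifted = t - c.collateral_delay_s - off
        bolus = bolus + gamma_variate(shifted, c.aif_t0_s, c.aif_alpha,
                                      c.aif_beta_s, c.aif_amplitude_hu)
        recirc = recirc + _recirculation(c, shifted)
    bolus = bolus / len(offsets)
    recirc = recirc / len(offsets)
    # only the first-pass bolus scales with the collateral fraction; the
    # blood-pool equilibrium reaches any perfused vessel, so the late-phase
    # term saturates once there is meaningful collateral flow (and vanishes
    # with no flow at all)
    retention = min(1.0, c.collateral_fraction / 0.2)
    return c.collateral_fraction * bolus + retention * recirc


def analytic_roi_tics(config: PhantomConfig,
                      rng: np.random.Generator | None = None,
                      noise_sd_hu: float = 0.0):
    """Arterial/venous ROI curves evaluated analytically at the frame times
    (no volume rasterization); vessel-volume curves are left missing.

    Convenient for exercising arrival detection, AV-ratio normalization and
    phase classification at scale.
    """
    from .curves import (ExtractionParams, TimeIntensityCurves,
                         av_ratio_curve, contrast_arrival)

    t = config.frame_times_s
    art = config.baseline_hu + arterial_enhancement(config, t)
    ven = config.baseline_hu + venous_enhancement(config, t)
    if noise_sd_hu > 0:
        if rng is None:
            raise ConfigurationError("noisy curves require an explicit rng")
        art = art + rng.normal(0.0, noise_sd_hu, size=art.shape)
        ven = ven + rng.normal(0.0, noise_sd_hu, size=ven.shape)
    ratio = av_ratio_curve(art, ven, config.baseline_hu)
    arrival = contrast_arrival(art, t, ExtractionParams())
    nanv = np.full_like(t, np.nan)
    return TimeIntensityCurves(
        times_s=t, vol_occluded_ml=nanv.copy(), vol_contralateral_ml=nanv.copy(),
        cr_percent=nanv.copy(), arterial_hu=art, venous_hu=ven,
        av_ratio=ratio, arrival_s=arrival, blood_hu=config.baseline_hu)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

# One hemisphere's vessel tree, given in voxel coordinates of the LEFT side
# (x < midplane): (start_vox, end_vox, radius_mm, branch amplitude factor).
_VESSEL_SEGMENTS = [
    ((24, 30, 16), (10, 30, 16), 4.5, 1.00),   # M1-like stem
    ((16, 30, 16), (16, 40, 19), 3.5, 0.85),
    ((16, 30, 16), (16, 20, 19), 3.5, 0.80),
    ((10, 30, 16), (9, 42, 21), 2.8, 0.60),
    ((10, 30, 16), (9, 20, 21), 2.8, 0.55),
    ((13, 30, 16), (12, 36, 23), 2.5, 0.45),
    ((20, 30, 16), (19, 24, 22), 2.5, 0.50),
]
_MCA_BOX = ((5, 27), (15, 47), (9, 25))        # inclusive voxel bounds, left side
_ARTERIAL_BLOB = ((42.0, 30.0, 5.0), 5.0)      # ICA-top blob, right side; (centre, radius mm)
_VENOUS_BLOB = ((31.5, 52.0, 12.0), 6.0)       # confluence-of-sinuses blob, midline


def _segment_distance_mm(points_mm: np.ndarray, a_mm: np.ndarray, b_mm: np.ndarray) -> np.ndarray:
    """Distance from each point to the line segment a-b, in mm."""
    ab = b_mm - a_mm
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points_mm - a_mm, axis=1)
    t = np.clip((points_mm - a_mm) @ ab / denom, 0.0, 1.0)
    proj = a_mm + t[:, None] * ab
    return np.linalg.norm(points_mm - proj, axis=1)


def _sphere_indices(shape, spacing, center_vox, radius_mm):
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    d = np.linalg.norm((idx - np.asarray(center_vox, float)) * np.asarray(spacing), axis=1)
    sel = d <= radius_mm
    return tuple(idx[sel].astype(int).T)


class PhantomModel:
    """Continuous (noise-free) enhancement model of one synthetic subject.

    Holds the static anatomy plus voxel index sets for the four enhancing
    structures, and can evaluate a noise-free volume at any time, simulate
    the noisy CTP series, or emit the region specification.
    """

    def __init__(self, config: PhantomConfig):
        self.config = config
        shape = tuple(config.grid_shape)
        spacing = np.asarray(config.voxel_size_mm, float)
        nx = shape[0]

        # brain ellipsoid
        idx = np.indices(shape).astype(float)
        center = (np.asarray(shape, float) - 1.0) / 2.0
        semi = np.asarray([shape[0] * 0.46, shape[1] * 0.46, shape[2] * 0.46])
        brain = (((idx[0] - center[0]) / semi[0]) ** 2
                 + ((idx[1] - center[1]) / semi[1]) ** 2
                 + ((idx[2] - center[2]) / semi[2]) ** 2) <= 1.0

        # left-hemisphere vessel voxels with amplitude factors, then exact mirror
        left_amp = np.zeros(shape, dtype=float)
        pts_vox = np.indices(shape).reshape(3, -1).T.astype(float)
        pts_mm = pts_vox * spacing
        for (a, b, r_mm, branch_amp) in _VESSEL_SEGMENTS:
            a_mm = np.asarray(a, float) * spacing
            b_mm = np.asarray(b, float) * spacing
            d = _segment_distance_mm(pts_mm, a_mm, b_mm)
            inside = d <= r_mm
            # radial partial-volume falloff: 1 on the axis, 0.3 at the wall,
            # shaped so voxel amplitudes are spread smoothly (heavy-tailed in
            # 1/amplitude) and enhanced volume varies smoothly with threshold
            s = (d[inside] / r_mm) ** 2          # ~uniform over the disc area
            pv = (1.0 + s * (0.3 ** -2 - 1.0)) ** -0.5
            fac = np.zeros(pts_mm.shape[0])
            fac[inside] = branch_amp * pv
            left_amp = np.maximum(left_amp, fac.reshape(shape))
        if left_amp[nx // 2:].any():
            raise ConfigurationError("vessel tree crosses the midplane; enlarge the grid")
        if not left_amp.any():
            raise ConfigurationError("vessel tree exceeds the grid")
        right_amp = left_amp[::-1, :, :].copy()   # mirror across the midsagittal plane

        (x0, x1), (y0, y1), (z0, z1) = _MCA_BOX
        left_box = np.zeros(shape, dtype=bool)
        left_box[x0:x1 + 1, y0:y1 + 1, z0:z1 + 1] = True
        right_box = left_box[::-1, :, :].copy()

        art_center, art_r = _ARTERIAL_BLOB
        if config.occlusion_side == "left":
            occ_amp, con_amp = left_amp, right_amp
            occ_box, con_box = left_box, right_box
            art_center_side = art_center                      # ICA top, non-occluded (right)
        else:
            occ_amp, con_amp = right_amp, left_amp
            occ_box, con_box = right_box, left_box
            art_center_side = (nx - 1 - art_center[0], art_center[1], art_center[2])

        self.occ_idx = np.nonzero(occ_amp)
        self.occ_amp = occ_amp[self.occ_idx]
        self.con_idx = np.nonzero(con_amp)
        self.con_amp = con_amp[self.con_idx]
        self.mca_occluded_mask = occ_box & brain
        self.mca_contralateral_mask = con_box & brain

        self.art_idx = _sphere_indices(shape, spacing, art_center_side, art_r)
        ven_center, ven_r = _VENOUS_BLOB
        self.ven_idx = _sphere_indices(shape, spacing, ven_center, ven_r)
        if len(self.art_idx[0]) == 0 or len(self.ven_idx[0]) == 0:
            raise ConfigurationError("ROI blob exceeds the grid")
        self.arterial_roi = SphereROI(art_center_side, 3.0)
        self.venous_roi = SphereROI(ven_center, 3.0)

        static = np.zeros(shape, dtype=np.float32)
        static[brain] = config.tissue_hu
        for ind in (self.occ_idx, self.con_idx, self.art_idx, self.ven_idx):
            static[ind] = config.baseline_hu
        self.static = static
        self.brain_mask = brain

    # -- enhancement curves (HU above blood baseline) -----------------------

    def arterial_enhancement(self, t):
        return arterial_enhancement(self.config, t)

    def venous_enhancement(self, t):
        return venous_enhancement(self.config, t)

    def occluded_enhancement(self, t):
        return occluded_enhancement(self.config, t)

    # -- volumes ------------------------------------------------------------

    def volume_at(self, t: float) -> np.ndarray:
        """Noise-free volume of the continuous enhancement model at time ``t``."""
        vol = self.static.copy()
        vol[self.con_idx] += (self.con_amp * float(self.arterial_enhancement(t))).astype(np.float32)
        vol[self.occ_idx] += (self.occ_amp * float(self.occluded_enhancement(t))).astype(np.float32)
        vol[self.art_idx] += np.float32(self.arterial_enhancement(t))
        vol[self.ven_idx] += np.float32(self.venous_enhancement(t))
        return vol

    def simulate_series(self, rng: np.random.Generator | None = None) -> CTPSeries:
        """Simulate the CTP acquisition with i.i.d. Gaussian HU noise."""
        c = self.config
        if rng is None:
            rng = np.random.default_rng(c.seed)
        times = c.frame_times_s
        data = np.stack([self.volume_at(t) for t in times])
        if c.noise_sd_hu > 0:
            data = data + rng.normal(0.0, c.noise_sd_hu, size=data.shape).astype(np.float32)
        return CTPSeries(data.astype(np.float32), times, c.voxel_size_mm)

    def roi_tics(self, rng: np.random.Generator | None = None,
                 noise_sd_hu: float = 0.0):
        return analytic_roi_tics(self.config, rng, noise_sd_hu)

    def region_spec(self) -> RegionSpec:
        return RegionSpec(
            mca_occluded_mask=self.mca_occluded_mask,
            mca_contralateral_mask=self.mca_contralateral_mask,
            arterial_roi=self.arterial_roi,
            venous_roi=self.venous_roi,
            occlusion_side=self.config.occlusion_side,
        )

    def ground_truth(self) -> GroundTruth:
        c = self.config
        return GroundTruth(
            occlusion_side=c.occlusion_side,
            collateral_fraction=c.collateral_fraction,
            true_arrival_s=c.aif_t0_s,
        )


def generate_phantom(config: PhantomConfig):
    """Build one phantom subject: ``(CTPSeries, RegionSpec, GroundTruth)``.

    Identical configurations (including seed) give bit-identical output.
    """
    model = PhantomModel(config)
    return model.simulate_series(), model.region_spec(), model.ground_truth()


def sample_mcta(model: PhantomModel,
                offset_s: float,
                delays_s: tuple[float, float],
                noise_sd_hu: float = 0.0,
                rng: np.random.Generator | None = None,
                truth: GroundTruth | None = None):
    """Sample three mCTA volumes from the continuous enhancement model.

    The volumes are evaluated at ``offset_s``, ``offset_s + delays_s[0]`` and
    ``offset_s + delays_s[0] + delays_s[1]`` on the CTP time axis. Noise-free
    by default; pass ``noise_sd_hu`` and a generator to add acquisition noise.

    Returns ``(volumes, times_s)``; if ``truth`` is given, its mCTA fields are
    updated in place.
    """
    delays_s = tuple(float(d) for d in delays_s)
    if len(delays_s) != 2 or any(d < 0 for d in delays_s):
        raise ConfigurationError("delays_s must be two non-negative gaps")
    times = [offset_s, offset_s + delays_s[0], offset_s + delays_s[0] + delays_s[1]]
    if offset_s < 0 or times[-1] > model.config.duration_s:
        raise ConfigurationError(
            f"mCTA sampling times {times} fall outside the acquisition (0, {model.config.duration_s}]"
        )
    volumes = [model.volume_at(t) for t in times]
    if noise_sd_hu > 0:
        if rng is None:
            raise ConfigurationError("noisy mCTA sampling requires an explicit rng")
        volumes = [v + rng.normal(0.0, noise_sd_hu, size=v.shape).astype(np.float32)
                   for v in volumes]
    if truth is not None:
        truth.true_mcta_offset_s = float(offset_s)
        truth.mcta_delays_s = delays_s
    return volumes, np.asarray(times)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Study conditions of the emulated cohort: collateral fractions span the
# full range; bolus-tracked mCTA baseline ~8.1 s after contrast arrival with
# ~8 s inter-acquisition delays; covariates linearly linked to the collateral
# fraction (better collaterals -> higher ASPECTS-like, lower NIHSS-like).
_CF_RANGE = (0.05, 1.0)
# retrograde filling is always slower than antegrade flow (the collateral
# route is longer), hence a floor delay plus a term growing as collateral
# supply worsens
_COLLATERAL_DELAY_BASE_S = 2.0
_COLLATERAL_DELAY_SLOPE_S = 3.0
_MCTA_OFFSET_AFTER_ARRIVAL_S = (8.1, 1.25)    # mean, sd
_MCTA_DELAY_S = (8.0, 0.75)                   # mean, sd
_ASPECTS_LINK = (4.0, 6.0)                    # intercept, slope on collateral fraction
_NIHSS_LINK = (25.0, -18.0)


def cohort_configs(n: int,
                   base_config: PhantomConfig | None = None,
                   seed: int = 0,
                   aspects_noise_sd: float = 1.0,
                   nihss_noise_sd: float = 3.0) -> list[tuple[PhantomConfig, GroundTruth]]:
    """Draw per-subject configurations and ground truth for a synthetic cohort.

    Subjects differ in collateral fraction (uniform on [0.05, 1]), collateral
    filling delay, occlusion side, mCTA timing and noise realization; the
    ASPECTS-like and NIHSS-like covariates are linear in the collateral
    fraction plus Gaussian noise, rounded and clipped to their scales.
    """
    if n < 2:
        raise ConfigurationError("a cohort needs at least 2 subjects")
    base = base_config if base_config is not None else PhantomConfig()
    out = []
    for i in range(n):
        ss = np.random.SeedSequence([int(seed), i])
        rng = np.random.default_rng(ss)
        cf = float(rng.uniform(*_CF_RANGE))
        side = "left" if rng.uniform() < 0.5 else "right"
        subject_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        cfg = replace(
            base,
            collateral_fraction=cf,
            collateral_delay_s=(_COLLATERAL_DELAY_BASE_S
                                + _COLLATERAL_DELAY_SLOPE_S * (1.0 - cf)),
            occlusion_side=side,
            seed=subject_seed,
        )
        offset = cfg.aif_t0_s + max(2.0, rng.normal(*_MCTA_OFFSET_AFTER_ARRIVAL_S))
        delays = tuple(max(2.0, rng.normal(*_MCTA_DELAY_S)) for _ in range(2))
        # keep the last mCTA inside the acquisition
        offset = min(offset, cfg.duration_s - sum(delays))
        a0, a1 = _ASPECTS_LINK
        n0, n1 = _NIHSS_LINK
        aspects = int(np.clip(round(a0 + a1 * cf + rng.normal(0.0, aspects_noise_sd)), 0, 10))
        nihss = int(np.clip(round(n0 + n1 * cf + rng.normal(0.0, nihss_noise_sd)), 0, 42))
        truth = GroundTruth(
            occlusion_side=side,
            collateral_fraction=cf,
            true_arrival_s=cfg.aif_t0_s,
            true_mcta_offset_s=float(offset),
            mcta_delays_s=delays,
            covariates={"aspects": aspects, "nihss": nihss},
        )
        out.append((cfg, truth))
    return out


def generate_cohort(n: int,
                    base_config: PhantomConfig | None = None,
                    seed: int = 0,
                    **covariate_kw):
    """Materialize a synthetic cohort: list of ``(CTPSeries, RegionSpec, GroundTruth)``.

    For large cohorts prefer :func:`cohort_configs` and build each
    :class:`PhantomModel` in turn; this convenience wrapper holds every
    series in memory at once.
    """
    out = []
    for cfg, truth in cohort_configs(n, base_config, seed, **covariate_kw):
        model = PhantomModel(cfg)
        out.append((model.simulate_series(), model.region_spec(), truth))
    return out
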