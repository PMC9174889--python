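"""Dynamic-speckle phantom generator.

Synthesizes every input the analysis pipeline consumes with known ground
truth: raw speckle frame stacks whose per-pixel statistics follow integrated
dynamic-speckle theory, stroke-scenario flow time courses, coronal section
stacks (neuron + vessel channels) for infarct volumetry and vascular density,
and transmitted beam-spot images.

The speckle model: at each pixel the optical field is a complex circular
Gaussian process with field autocorrelation |g1(tau)| = exp(-tau/tau_c),
where tau_c is the decorrelation time set by the local scatterer (red blood
cell) speed via tau_c = a / v.  A camera frame integrates intensity |E|^2
over the exposure T, so the ensemble temporal contrast K = sigma_I / <I>
obeys the closed form

    K^2(x) = (exp(-2x) - 1 + 2x) / (2 x^2),   x = T / tau_c,

which is the oracle every simulation is validated against.  Faster flow ->
shorter tau_c -> larger x -> lower contrast, and in the x >> 1 regime
1/K^2 ~ x is proportional to speed, which is what makes the 1/Kt^2 flow
index a linear surrogate of relative blood flow.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "FlowMap",
    "StrokeScenario",
    "SpeckleStack",
    "SectionStack",
    "BeamScene",
    "VesselSegment",
    "make_flow_map",
    "simulate_speckle_stack",
    "integrated_contrast",
    "apply_scenario",
    "make_section_stack",
    "make_beam_scene",
    "short_term_scenario",
    "dose_recovery_scenario",
    "TAU_STATIC_SENTINEL",
]

#: sentinel decorrelation time for truly frozen (static) scatterers, ms
TAU_STATIC_SENTINEL = np.inf

#: residual decorrelation time of "no-flow" tissue, ms.  Tissue with zero
#: perfusion still shows slow dynamics (Brownian motion, physiological
#: motion); a literally frozen field would make temporal contrast zero and
#: the flow index diverge.
TAU_NOFLOW_MS = 200.0

COMPARTMENTS = (
    "core",
    "large_vessel",
    "small_vessel",
    "outside_vessel",
    "parenchyma",
    "static",
)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera acquisition parameters for one speckle stack.

    Defaults mirror a typical temporal-contrast protocol: 40 frames of
    20 ms exposure.  ``frame_interval`` is the start-to-start frame spacing;
    the field keeps evolving in the readout gap between frames.
    """

    n_frames: int = 40
    exposure_T: float = 20.0  # ms
    frame_interval: float = 25.0  # ms
    pixel_size: float = 0.02  # mm / pixel
    bit_depth: int = 16
    noise_model: Literal["none", "gaussian", "poisson"] = "none"
    noise_param: float = 0.0  # sd for gaussian, gain for poisson
    g1_model: Literal["exponential", "gaussian"] = "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.exposure_T <= 0:
            raise ValueError("exposure_T must be positive")
        if self.exposure_T > self.frame_interval:
            raise ValueError("exposure_T must not exceed frame_interval")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class FlowMap:
    """Latent per-pixel flow state of the phantom.

    ``speed`` is in arbitrary velocity units (the imaging modality is
    relative-only); ``tau_c`` in ms derives from it as a / v, capped at the
    residual no-flow decorrelation time; ``label`` partitions the image
    into scenario compartments.
    """

    speed: np.ndarray
    tau_c: np.ndarray
    label: np.ndarray  # array of compartment strings
    pixel_size: float  # mm / pixel
    calibration_a: float = 1.0  # ms * a.u.

    def __post_init__(self) -> None:
        if self.speed.shape != self.tau_c.shape or self.speed.shape != self.label.shape:
            raise ValueError("speed, tau_c and label must share one shape")
        moving = self.speed > 0
        if np.any(self.tau_c[moving] <= 0):
            raise ValueError("tau_c must be positive wherever speed > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.speed.shape

    def copy(self) -> "FlowMap":
        return FlowMap(
            self.speed.copy(),
            self.tau_c.copy(),
            self.label.copy(),
            self.pixel_size,
            self.calibration_a,
        )


def _tau_from_speed(speed: np.ndarray, a: float) -> np.ndarray:
    """tau_c = a / v, capped at the residual no-flow decorrelation time."""
    with np.errstate(divide="ignore"):
        tau = np.where(speed > 0, a / np.maximum(speed, 1e-300), np.inf)
    return np.minimum(tau, TAU_NOFLOW_MS)


@dataclass(frozen=True)
class VesselSegment:
    """A straight vessel: endpoints in mm (row, col), width in mm."""

    start_mm: tuple[float, float]
    end_mm: tuple[float, float]
    width_mm: float
    speed: float
    label: str = "large_vessel"


def make_flow_map(
    width_px: int,
    height_px: int,
    pixel_size: float,
    vessel_spec: Sequence[VesselSegment] = (),
    parenchyma_speed: float = 1.0,
    calibration_a: float = 1.0,
    spot_center_mm: tuple[float, float] | None = None,
    spot_diameter_mm: float = 1.0,
    seed: int | None = None,
) -> FlowMap:
    """Rasterize a vessel/parenchyma phantom geometry into a FlowMap.

    Vessels are line segments with a physical width, drawn over a uniform
    parenchyma background.  If ``spot_center_mm`` (row, col in mm from the
    image origin) is given, pixels inside the irradiation spot that are not
    vessels are labelled ``core`` so stroke scenarios can target them.

    Parameters are physical (mm); the pixel raster uses pixel centers at
    (i + 0.5) * pixel_size.
    """
    if parenchyma_speed <= 0:
        raise ValueError("parenchyma_speed must be positive (perfused tissue)")
    h, w = int(height_px), int(width_px)
    speed = np.full((h, w), float(parenchyma_speed))
    label = np.full((h, w), "parenchyma", dtype=object)

    rows = (np.arange(h) + 0.5) * pixel_size
    cols = (np.arange(w) + 0.5) * pixel_size
    rr, cc = np.meshgrid(rows, cols, indexing="ij")

    if spot_center_mm is not None:
        r0, c0 = spot_center_mm
        inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= (spot_diameter_mm / 2.0) ** 2
        label[inside] = "core"

    for seg in vessel_spec:
        if seg.width_mm > min(h, w) * pixel_size:
            raise ValueError(f"vessel wider than image: {seg.width_mm} mm")
        if seg.speed <= 0:
            raise ValueError("vessel speed must be positive")
        if seg.label not in COMPARTMENTS:
            raise ValueError(f"unknown compartment label {seg.label!r}")
        p0 = np.asarray(seg.start_mm, dtype=float)
        p1 = np.asarray(seg.end_mm, dtype=float)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            raise ValueError("degenerate vessel segment (zero length)")
        # distance from each pixel center to the segment
        t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
        on = dist <= seg.width_mm / 2.0
        speed[on] = seg.speed
        label[on] = seg.label

    tau = _tau_from_speed(speed, calibration_a)
    return FlowMap(speed, tau, label, pixel_size, calibration_a)


# ---------------------------------------------------------------------------
# speckle synthesis


def integrated_contrast(x: np.ndarray | float) -> np.ndarray | float:
    """Closed-form exposure-integrated speckle contrast K(x), x = T / tau_c.

    K^2(x) = (exp(-2x) - 1 + 2x) / (2 x^2) for an exponential field
    autocorrelation and unit coherence factor; K(0) = 1 (frozen speckle).
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x > 0
    xn = x[nz]
    out[nz] = (np.expm1(-2.0 * xn) + 2.0 * xn) / (2.0 * xn**2)
    out = np.sqrt(out)
    return float(out) if out.ndim == 0 else out


@dataclass
class SpeckleStack:
    """N raw speckle frames plus acquisition metadata (and optional truth)."""

    frames: np.ndarray  # (N, H, W) non-negative
    config: AcquisitionConfig
    truth: FlowMap | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (N, H, W)")
        if self.frames.shape[0] != self.config.n_frames:
            raise ValueError("frame count must equal config.n_frames")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _ar_rho(dt: float | np.ndarray, tau: np.ndarray, model: str) -> np.ndarray:
    """Step correlation of the complex field over an interval dt."""
    with np.errstate(divide="ignore"):
        r = np.asarray(dt) / tau
    if model == "gaussian":
        return np.exp(-0.5 * r**2)
    return np.exp(-r)


def _simulate_group(
    rng: np.random.Generator,
    tau: float,
    n_px: int,
    config: AcquisitionConfig,
    substep_ms: float | None,
) -> np.ndarray:
    """Frame intensities (n_frames, n_px) for pixels sharing one tau_c."""
    from scipy.signal import lfilter

    T = config.exposure_T
    dt_raw = min(tau / 8.0, T / 16.0) if substep_ms is None else substep_ms
    n_sub = max(2, int(np.ceil(T / min(dt_raw, T)))) if np.isfinite(dt_raw) else 16
    dt = T / n_sub
    tau_arr = np.array([tau])
    rho = float(_ar_rho(dt, tau_arr, config.g1_model)[0])
    # the last in-frame sample sits at (n_sub-1)*dt after frame start, so the
    # jump to the next frame's first sample spans interval - (n_sub-1)*dt
    jump = config.frame_interval - (n_sub - 1) * dt
    rho_gap = float(_ar_rho(jump, tau_arr, config.g1_model)[0])

    def cgauss(shape) -> np.ndarray:
        g = rng.standard_normal((2,) + tuple(np.atleast_1d(shape)), dtype=np.float32)
        return ((g[0] + 1j * g[1]) * np.float32(1.0 / np.sqrt(2.0))).astype(np.complex64)

    E = cgauss(n_px)
    s_sub = np.float32(np.sqrt(max(0.0, 1.0 - rho**2)))
    s_gap = np.float32(np.sqrt(max(0.0, 1.0 - rho_gap**2)))
    b = np.array([1.0], dtype=np.float32)
    a = np.array([1.0, -rho], dtype=np.float32)
    frames = np.empty((config.n_frames, n_px))
    for k in range(config.n_frames):
        if n_sub > 1 and s_sub > 0:
            xi = s_sub * cgauss((n_sub - 1, n_px))
            zi = (np.float32(rho) * E)[None, :]
            y, _ = lfilter(b, a, xi, axis=0, zi=zi)
            acc = np.abs(E) ** 2 + np.einsum("ij,ij->j", y.real, y.real) + np.einsum(
                "ij,ij->j", y.imag, y.imag
            )
            frames[k] = acc / n_sub
            E = y[-1]
        else:  # frozen within the frame
            frames[k] = np.abs(E) ** 2
        if k < config.n_frames - 1:
            E = np.float32(rho_gap) * E + s_gap * cgauss(n_px)
    return frames


def simulate_speckle_stack(
    flow_map: FlowMap,
    config: AcquisitionConfig,
    substep_ms: float | None = None,
    mean_intensity: float = 1000.0,
) -> SpeckleStack:
    """Synthesize a speckle frame stack from a flow map.

    Per pixel an AR(1) complex circular-Gaussian field with step correlation
    exp(-dt/tau_c) is advanced on a sub-step grid; each frame's intensity is
    the mean of |E|^2 over the sub-steps spanning the exposure, and the field
    is advanced in one exact AR jump across the readout gap between frames,
    so it evolves continuously over the whole acquisition.  Detector noise,
    if configured, is applied last.

    The sub-step defaults to min(tau_c / 8, T / 16), chosen per group of
    pixels sharing a tau_c (the recursion runs group-wise through a C-level
    IIR filter); a caller-supplied sub-step coarser than tau_c / 4 raises
    (undersampled dynamics would bias the frame statistics).
    """
    tau = np.asarray(flow_map.tau_c, dtype=float)
    finite = np.isfinite(tau)
    tau_min = float(tau[finite].min()) if finite.any() else np.inf
    if substep_ms is not None:
        if substep_ms <= 0:
            raise ValueError("sub-step must be positive")
        if substep_ms > tau_min / 4.0:
            raise ValueError(
                f"sub-step {substep_ms} ms undersamples dynamics (tau_c_min = {tau_min} ms);"
                " need <= tau_c/4"
            )

    rng = np.random.default_rng(config.seed)
    h, w = tau.shape
    tau_flat = tau.reshape(-1)
    frames = np.empty((config.n_frames, h * w))
    # deterministic group order: unique sorted tau values (inf = frozen last)
    for tv in np.unique(tau_flat):
        sel = np.flatnonzero(tau_flat == tv)
        if np.isfinite(tv):
            frames[:, sel] = _simulate_group(rng, float(tv), sel.size, config, substep_ms)
        else:  # frozen-field sentinel: one static realization per pixel
            E = (rng.standard_normal(sel.size) + 1j * rng.standard_normal(sel.size)) / np.sqrt(2)
            frames[:, sel] = np.abs(E)[None, :] ** 2

    frames = frames.reshape(config.n_frames, h, w) * mean_intensity
    if config.noise_model == "gaussian":
        frames = frames + rng.normal(0.0, config.noise_param, frames.shape)
        frames = np.clip(frames, 0.0, None)
    elif config.noise_model == "poisson":
        gain = config.noise_param if config.noise_param > 0 else 1.0
        frames = rng.poisson(frames / gain).astype(float) * gain
    return SpeckleStack(frames, config, truth=flow_map)


# ---------------------------------------------------------------------------
# stroke scenarios


@dataclass
class StrokeScenario:
    """Per-compartment flow-multiplier time courses, parameterized by dose.

    ``timeline`` maps a compartment label to a list of (time, multiplier)
    breakpoints; multipliers are interpolated piecewise-linearly between
    breakpoints.  At time 0 every multiplier is 1 (pre-stroke baseline).
    Times are in whatever unit the scenario declares (hours for the acute
    course, days for the two-week course).
    """

    dose_minutes: float
    timeline: dict[str, list[tuple[float, float]]]
    time_unit: str = "h"
    spot_center_ap_ml: tuple[float, float] = (-2.0, 2.0)  # bregma-relative mm
    spot_diameter_mm: float = 1.0
    eval_circle_diameter_mm: float = 2.0

    def __post_init__(self) -> None:
        for lbl, pts in self.timeline.items():
            if lbl not in COMPARTMENTS:
                raise ValueError(f"unknown compartment label {lbl!r}")
            pts.sort(key=lambda p: p[0])
            t0, m0 = pts[0]
            if t0 == 0 and abs(m0 - 1.0) > 1e-12:
                raise ValueError(f"multiplier at t=0 must be 1 for {lbl!r}")
            if any(m < 0 for _, m in pts):
                raise ValueError("multipliers must be non-negative")
        if self.dose_minutes == 0:
            for lbl, pts in self.timeline.items():
                if any(not (0.9 <= m <= 1.1) for _, m in pts):
                    raise ValueError(
                        "light-only control (dose 0) must keep multipliers in [0.9, 1.1]"
                    )

    def multiplier(self, label: str, t: float) -> float:
        """Piecewise-linear multiplier for one compartment at time t."""
        pts = self.timeline.get(label)
        if pts is None:
            return 1.0
        times = [p[0] for p in pts]
        if not (times[0] <= t <= times[-1]):
            raise ValueError(
                f"t = {t} outside timeline range [{times[0]}, {times[-1]}] for {label!r}"
            )
        return float(np.interp(t, times, [p[1] for p in pts]))


def apply_scenario(flow_map: FlowMap, scenario: StrokeScenario, t: float) -> FlowMap:
    """Return a new FlowMap with compartment speeds scaled by the scenario at t.

    Speeds are multiplied per compartment label; tau_c is recomputed from the
    scaled speeds (the spatial restriction to the spot / evaluation circle is
    carried by the labels the flow map was built with).
    """
    out = flow_map.copy()
    labels_present = set(np.unique(flow_map.label))
    unknown = labels_present - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"unknown compartment labels in flow map: {sorted(unknown)}")
    for lbl in labels_present:
        m = scenario.multiplier(lbl, t)
        if m != 1.0:
            sel = flow_map.label == lbl
            out.speed[sel] = flow_map.speed[sel] * m
    out.tau_c = _tau_from_speed(out.speed, out.calibration_a)
    # preserve frozen-field sentinel pixels
    out.tau_c[flow_map.label == "static"] = TAU_STATIC_SENTINEL
    return out


def short_term_scenario(dose_minutes: float = 2.0) -> StrokeScenario:
    """Acute 6-hour post-occlusion course (times in hours).

    Compartment courses: the irradiated core falls to 50% of baseline at 2 h
    and ~30% by 6 h; large in-spot vessels fall to ~50% by 3 h then plateau;
    small in-spot vessels fall faster (50% at 1.5 h, ~20% at 6 h); vessels
    outside the spot decline slowly and slightly.  Dose 0 is the light-only
    control with all compartments held at baseline.
    """
    if dose_minutes == 0:
        tl = {lbl: [(0.0, 1.0), (6.0, 1.0)] for lbl in COMPARTMENTS if lbl != "static"}
        return StrokeScenario(0.0, tl, time_unit="h")
    tl = {
        "core": [(0.0, 1.0), (2.0, 0.5), (6.0, 0.3)],
        "parenchyma": [(0.0, 1.0), (6.0, 1.0)],
        "large_vessel": [(0.0, 1.0), (3.0, 0.5), (6.0, 0.5)],
        "small_vessel": [(0.0, 1.0), (1.5, 0.5), (6.0, 0.2)],
        "outside_vessel": [(0.0, 1.0), (6.0, 0.9)],
    }
    return StrokeScenario(dose_minutes, tl, time_unit="h")


#: mean relative CBF in the 2-mm evaluation circle on days 1/4/7/14 by dose
_RECOVERY_COURSE = {
    5.0: [(0.0, 1.0), (1.0, 0.0), (4.0, 0.0), (7.0, 0.38), (14.0, 0.64)],
    2.0: [(0.0, 1.0), (1.0, 0.27), (4.0, 0.69), (7.0, 0.84), (14.0, 1.0)],
    1.0: [(0.0, 1.0), (1.0, 0.39), (4.0, 0.84), (7.0, 1.07), (14.0, 0.94)],
    0.0: [(0.0, 1.0), (14.0, 1.0)],
}


def dose_recovery_scenario(dose_minutes: float) -> StrokeScenario:
    """14-day dose-dependent recovery course (times in days).

    The multiplier course for the irradiated region follows the measured
    evaluation-circle means for each light dose: the 5-min dose abolishes
    flow for days then partially recovers (0.64 of baseline by day 14),
    lighter doses recover faster and fully.  Applied to every in-circle
    compartment; tissue outside stays at baseline.
    """
    if dose_minutes not in _RECOVERY_COURSE:
        raise ValueError(f"dose must be one of {sorted(_RECOVERY_COURSE)} minutes")
    course = [tuple(p) for p in _RECOVERY_COURSE[dose_minutes]]
    tl = {
        "core": list(course),
        "large_vessel": list(course),
        "small_vessel": list(course),
        "parenchyma": [(0.0, 1.0), (14.0, 1.0)],
        "outside_vessel": [(0.0, 1.0), (14.0, 1.0)],
    }
    return StrokeScenario(dose_minutes, tl, time_unit="d")


# ---------------------------------------------------------------------------
# section stacks


@dataclass
class SectionStack:
    """Ordered coronal sections: neuron-stain images + vessel masks."""

    neuron_channel: list[np.ndarray]
    vessel_channel: list[np.ndarray]
    slice_spacing_h: float  # micrometers
    pixel_size: float  # mm / pixel
    truth_infarct_masks: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.neuron_channel) != len(self.vessel_channel):
            raise ValueError("channels must have the same number of slices")
        for a, b in zip(self.neuron_channel, self.vessel_channel):
            if a.shape != b.shape:
                raise ValueError("channel slices must share one shape")
        if self.slice_spacing_h <= 0:
            raise ValueError("slice spacing must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.neuron_channel)

    @property
    def truth_volume_mm3(self) -> float | None:
        if self.truth_infarct_masks is None:
            return None
        area = sum(int(m.sum()) for m in self.truth_infarct_masks)
        return area * self.pixel_size**2 * (self.slice_spacing_h / 1000.0)


def _disk_mask(shape: tuple[int, int], center_px: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px**2


def _mask_with_exact_count(shape: tuple[int, int], center: tuple[float, float], n_px: int) -> np.ndarray:
    """Binary mask of exactly n_px pixels, grown as a disk around center."""
    if n_px <= 0:
        return np.zeros(shape, dtype=bool)
    if n_px > shape[0] * shape[1]:
        raise ValueError("requested more pixels than the image holds")
    rr, cc = np.indices(shape)
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    mask = np.zeros(shape[0] * shape[1], dtype=bool)
    mask[order[:n_px]] = True
    return mask.reshape(shape)


def make_section_stack(
    n_slices: int = 30,
    slice_spacing_h: float = 100.0,
    pixel_size: float = 0.02,
    shape: tuple[int, int] = (256, 256),
    target_volume_mm3: float = 0.0,
    density_truths: tuple[float, float] = (0.12, 0.10),
    roi_size_mm: float = 1.0,
    stain_level: float = 0.8,
    seed: int = 0,
) -> SectionStack:
    """Build a synthetic coronal section stack with exact measured truths.

    The neuron channel carries an unstained (near-zero) infarct region per
    slice whose areas follow an ellipsoidal-cap axial profile scaled so that
    sum(area * h) equals ``target_volume_mm3`` to within one pixel-area x h
    quantum (areas are realized as exact pixel counts).  The vessel channel
    carries binary masks whose vascular-area fraction inside the 1 mm x 1 mm
    evaluation ROIs equals ``density_truths`` (ipsilateral, contralateral)
    exactly at pixel resolution.
    """
    if target_volume_mm3 < 0:
        raise ValueError("target volume must be non-negative")
    if not all(0.0 <= d <= 1.0 for d in density_truths):
        raise ValueError("density truths must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h_mm = slice_spacing_h / 1000.0
    px_area = pixel_size**2
    H, W = shape

    # ellipsoidal-cap axial area profile: area_i ∝ 1 - z_i^2 on z in (-1, 1)
    z = np.linspace(-1.0, 1.0, n_slices + 2)[1:-1]
    profile = np.clip(1.0 - z**2, 0.0, None)
    if target_volume_mm3 > 0:
        areas = profile / profile.sum() * (target_volume_mm3 / h_mm)
        counts = np.round(areas / px_area).astype(int)
        # adjust the largest slice so the realized total matches the target
        # to within one voxel quantum
        deficit = int(round(target_volume_mm3 / (px_area * h_mm))) - counts.sum()
        counts[np.argmax(counts)] += deficit
        if counts.min() < 0:
            raise ValueError("target volume unachievable at this resolution")
        max_count = _disk_mask(shape, (H / 2, W / 2), min(H, W) / 2 - 2).sum()
        if counts.max() > max_count:
            raise ValueError("target volume unachievable at this resolution")
    else:
        counts = np.zeros(n_slices, dtype=int)

    # evaluation ROIs: ipsilateral left-center, contralateral right-center
    # (clamped into the image; they overlap if the image is too small to
    # hold both, which only matters when density truths are being measured)
    roi_px = min(int(round(roi_size_mm / pixel_size)), H, W)

    def _roi_slices(col_center: int) -> tuple[slice, slice]:
        r0 = min(max(H // 2 - roi_px // 2, 0), H - roi_px)
        c0 = min(max(col_center - roi_px // 2, 0), W - roi_px)
        return slice(r0, r0 + roi_px), slice(c0, c0 + roi_px)

    ipsi = _roi_slices(W // 4)
    contra = _roi_slices(3 * W // 4)

    neuron, vessel, truths = [], [], []
    for i in range(n_slices):
        img = np.full(shape, stain_level) + rng.normal(0.0, 0.02, shape)
        img = np.clip(img, 0.0, 1.0)
        infarct = _mask_with_exact_count(shape, (H / 2, W / 4), int(counts[i]))
        img[infarct] = np.clip(rng.normal(0.02, 0.005, int(infarct.sum())), 0.0, None)
        neuron.append(img)
        truths.append(infarct)

        vmask = np.zeros(shape, dtype=bool)
        for roi, dens in zip((ipsi, contra), density_truths):
            block = np.zeros((roi_px, roi_px), dtype=bool)
            n_on = int(round(dens * roi_px * roi_px))
            # deterministic vessel-like fill: full rows then a partial row
            full, rem = divmod(n_on, roi_px)
            stride = max(1, roi_px // max(full, 1)) if full else roi_px
            placed = 0
            for r in range(0, roi_px, stride):
                if placed >= full:
                    break
                block[r, :] = True
                placed += 1
            if placed < full:  # stride overflow fallback
                off = block.sum()
                flat = block.ravel()
                flat[np.flatnonzero(~flat)[: full * roi_px - off]] = True
                block = flat.reshape(roi_px, roi_px)
            if rem:
                free_rows = [r for r in range(roi_px) if not block[r].any()]
                rr_ = free_rows[len(free_rows) // 2] if free_rows else 0
                block[rr_, :rem] = True
            if int(block.sum()) != n_on:  # exactness guard
                flat = block.ravel()
                diff = n_on - int(block.sum())
                if diff > 0:
                    flat[np.flatnonzero(~flat)[:diff]] = True
                else:
                    flat[np.flatnonzero(flat)[:(-diff)]] = False
                block = flat.reshape(roi_px, roi_px)
            vmask[roi] = block
        vessel.append(vmask)

    return SectionStack(neuron, vessel, slice_spacing_h, pixel_size, truths)


# ---------------------------------------------------------------------------
# beam scenes


@dataclass
class BeamScene:
    """A synthetic transmitted beam-spot image with analytic ground truth."""

    image: np.ndarray
    center_px: tuple[float, float]
    pixel_size: float  # mm / pixel
    truth_half_radius_mm: float
    truth_total_power: float

    def __post_init__(self) -> None:
        if np.any(self.image < 0):
            raise ValueError("intensity must be non-negative")
        r, c = self.center_px
        if not (0 <= r < self.image.shape[0] and 0 <= c < self.image.shape[1]):
            raise ValueError("center must lie inside the image")


def make_beam_scene(
    profile: Literal["gaussian", "top-hat", "gaussian-plus-halo"],
    pixel_size: float = 0.01,
    shape: tuple[int, int] = (512, 512),
    sigma_mm: float = 0.4926,
    radius_mm: float = 0.5,
    halo_fraction: float = 0.2,
    halo_sigma_mm: float = 1.5,
    total_power: float = 1.0,
    background: float = 0.0,
    seed: int = 0,
) -> BeamScene:
    """Render an analytic beam-spot phantom.

    Gaussian: I(r) = I0 exp(-r^2 / (2 s^2)), half-maximum radius
    s * sqrt(2 ln 2).  Top-hat: uniform disk, half radius at the edge.
    gaussian-plus-halo adds a broad Gaussian pedestal (scattered light)
    carrying ``halo_fraction`` of the power.  The image integrates to
    ``total_power`` (before any constant background is added).
    """
    H, W = shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    rr, cc = np.indices(shape)
    r_mm = np.hypot(rr - cy, cc - cx) * pixel_size

    if profile == "gaussian":
        img = np.exp(-(r_mm**2) / (2.0 * sigma_mm**2))
        half = sigma_mm * np.sqrt(2.0 * np.log(2.0))
    elif profile == "top-hat":
        img = (r_mm <= radius_mm).astype(float)
        half = radius_mm
    elif profile == "gaussian-plus-halo":
        core = np.exp(-(r_mm**2) / (2.0 * sigma_mm**2))
        halo = np.exp(-(r_mm**2) / (2.0 * halo_sigma_mm**2))
        core /= core.sum()
        halo /= halo.sum()
        img = (1.0 - halo_fraction) * core + halo_fraction * halo
        # half radius of the composite profile, solved numerically
        r_grid = np.linspace(0.0, r_mm.max(), 20000)
        c_pk = (1.0 - halo_fraction) / (2 * np.pi * sigma_mm**2)
        h_pk = halo_fraction / (2 * np.pi * halo_sigma_mm**2)
        vals = c_pk * np.exp(-(r_grid**2) / (2 * sigma_mm**2)) + h_pk * np.exp(
            -(r_grid**2) / (2 * halo_sigma_mm**2)
        )
        half = float(r_grid[np.argmax(vals <= vals[0] / 2.0)])
    else:
        raise ValueError(f"unknown profile {profile!r}")

    if img.max() <= 0 or not np.isfinite(img).all():
        raise ValueError("profile undefined at the requested size")
    img = img / img.sum() * total_power + background
    return BeamScene(img, (cy, cx), pixel_size, half, total_power)
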