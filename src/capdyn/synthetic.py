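"""Synthetic fluorescence data with analytic ground truth.

Four generators emulate the data the pipeline quantifies:

* ``simulate_cap_movie`` — a 4D (t, z, y, x) movie of cortical actin caps on a
  lattice, each following the four-phase life history (exponential expansion,
  stabilization, elongation, fragmentation), with a frozen speckle field for
  intensity heterogeneity, one-sided axial falloff below the apical surface,
  and additive Gaussian noise. The default expansion rate gives a ~6-fold
  area increase over the 120 s expansion phase.
* ``simulate_frap_experiment`` — raw bleached-cap / reference-cap / background
  series constructed so that reference-cap normalization recovers an exact
  two-phase association curve (plus optional proportional noise).
* ``simulate_coloc_scene`` — a two-channel puncta image in which every punctum
  pair has an exactly specified pixel area and shared-pixel overlap.
* ``simulate_fallout_dataset`` — per-condition tables with a linear
  fallout-rate vs. expansion-rate relationship plus Gaussian noise.

Every generator is a pure function of its config (same seed => bit-identical
output) and returns ground truth for every quantity the pipeline estimates.

Caps are rendered as flat-top ellipses with a 2 px Gaussian edge roll-off
whose half-maximum contour encloses exactly the analytic area; ground-truth
mean/SD are measured on the flat-top interior, where the profile is constant,
so they are controlled quantities (SD = 0 when the speckle amplitude is 0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ParameterError, SceneError
from .frap import FrapTrace, two_phase_association
from .stack_io import ImageStack4D

__all__ = [
    "SceneConfig", "GroundTruth", "simulate_cap_movie", "truth_track",
    "FrapSimParams", "simulate_frap_experiment",
    "PunctumSpec", "ColocSceneConfig", "ColocScene", "simulate_coloc_scene",
    "FalloutSimConfig", "simulate_fallout_dataset",
]

EDGE_SIGMA_PX = 2.0
_HALF_WIDTH_PX = EDGE_SIGMA_PX * math.sqrt(2.0 * math.log(2.0))  # half-max offset

PHASES = ("expansion", "stabilization", "elongation", "fragmentation")


# ---------------------------------------------------------------------------
# cap movie


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic cap movie.

    The default schedule is 120 s expansion / 90 s stabilization / 60 s
    elongation / 60 s fragmentation at 5 s/frame, 15 z planes at 0.3 um, with
    the growth rate ``ln(6)/120`` per second so the cap area expands sixfold
    over the expansion phase.
    """

    n_frames: int = 67
    n_z: int = 15
    shape_yx: tuple[int, int] = (224, 224)
    pixel_size_um: float = 0.25
    frame_interval_s: float = 5.0
    z_step_um: float = 0.3
    n_caps: int = 4
    cap_spacing_um: float = 26.0
    expansion_s: float = 120.0
    stabilization_s: float = 90.0
    elongation_s: float = 60.0
    fragmentation_s: float = 60.0
    initial_area_um2: float = 34.0
    growth_rate_per_s: float = math.log(6.0) / 120.0
    max_area_um2: float = math.inf
    aspect_rate_per_s: float = 0.05       # aspect-ratio increase during elongation
    max_aspect: float = 2.0               # elongation ramp saturates here
    frag_decay_per_s: float = 0.01        # area decay rate during fragmentation
    cap_intensity: float = 2000.0
    background: float = 200.0
    het_amplitude: float = 120.0          # speckle-field SD inside the cap
    het_frag_scale: float = 0.5           # speckle amplitude factor after fragmentation
    noise_sd: float = 30.0
    axial_scale_um: float = 1.2           # Gaussian axial falloff below the surface
    apical_z: int = 2                     # shallowest plane with signal
    plane_offset_um: float = 0.9          # cap plane sits this far below apical_z
    n_holes: int = 3
    hole_radius_px: float = 2.0
    drift_sd_um: float = 0.05             # per-frame centroid random-walk step
    seed: int = 0

    def validate(self) -> None:
        for name in ("expansion_s", "stabilization_s", "elongation_s", "fragmentation_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.initial_area_um2 <= 0:
            raise ParameterError("initial_area_um2 must be > 0")
        if not self.cap_intensity > self.background >= 0:
            raise ParameterError("need cap_intensity > background >= 0")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0 or self.z_step_um <= 0:
            raise ParameterError("pixel/time/z steps must be > 0")
        if self.n_caps < 1:
            raise ParameterError("n_caps must be >= 1")
        if self.het_amplitude < 0 or self.noise_sd < 0:
            raise ParameterError("noise amplitudes must be >= 0")
        offset_planes = round(self.plane_offset_um / self.z_step_um)
        if self.apical_z < 0 or self.apical_z + offset_planes >= self.n_z:
            raise ParameterError("apical_z + plane offset must fit inside the z range")
        self._layout()  # raises SceneError if caps do not fit

    # geometric schedule -----------------------------------------------------
    @property
    def phase_starts_s(self) -> dict[str, float]:
        t1 = self.expansion_s
        t2 = t1 + self.stabilization_s
        t3 = t2 + self.elongation_s
        return {"expansion": 0.0, "stabilization": t1, "elongation": t2,
                "fragmentation": t3}

    def phase_of(self, t: float) -> str:
        starts = self.phase_starts_s
        if t < starts["stabilization"] or self.stabilization_s + self.elongation_s \
                + self.fragmentation_s == 0:
            return "expansion"
        if t < starts["elongation"] or self.elongation_s + self.fragmentation_s == 0:
            return "stabilization"
        if t < starts["fragmentation"] or self.fragmentation_s == 0:
            return "elongation"
        return "fragmentation"

    def area_at(self, t: float) -> float:
        """Analytic cap area (um^2) at time t seconds."""
        starts = self.phase_starts_s
        a_exp = lambda tt: min(self.initial_area_um2 * math.exp(self.growth_rate_per_s * tt),
                               self.max_area_um2)
        phase = self.phase_of(t)
        if phase == "expansion":
            return a_exp(min(t, self.expansion_s))
        plateau = a_exp(self.expansion_s)
        if phase in ("stabilization", "elongation"):
            return plateau
        return plateau * math.exp(-self.frag_decay_per_s * (t - starts["fragmentation"]))

    def aspect_at(self, t: float) -> float:
        starts = self.phase_starts_s
        if t <= starts["elongation"] or self.elongation_s == 0:
            return 1.0
        dt = min(t, starts["fragmentation"]) - starts["elongation"]
        return min(1.0 + self.aspect_rate_per_s * dt, self.max_aspect)

    @property
    def elongation_onset_frame(self) -> int:
        return int(round(self.phase_starts_s["elongation"] / self.frame_interval_s))

    def _layout(self) -> np.ndarray:
        """Cap lattice centers in pixels; raises SceneError if they don't fit."""
        ny, nx = self.shape_yx
        spacing_px = self.cap_spacing_um / self.pixel_size_um
        n_cols = math.ceil(math.sqrt(self.n_caps))
        n_rows = math.ceil(self.n_caps / n_cols)
        r0_px = math.sqrt(self.initial_area_um2 / math.pi) / self.pixel_size_um
        # largest radius over the whole schedule (area peaks at end of expansion)
        a_max = self.area_at(self.expansion_s)
        aspect_max = self.aspect_at(self.phase_starts_s["fragmentation"])
        r_max_px = (math.sqrt(a_max / math.pi) / self.pixel_size_um
                    * math.sqrt(aspect_max))
        margin = r_max_px + _HALF_WIDTH_PX + 2
        span_y = (n_rows - 1) * spacing_px
        span_x = (n_cols - 1) * spacing_px
        if span_y + 2 * margin > ny or span_x + 2 * margin > nx:
            raise SceneError(
                f"field {ny}x{nx} px too small for {self.n_caps} caps at spacing "
                f"{spacing_px:.1f} px with maximum cap radius {r_max_px:.1f} px")
        if spacing_px < 2 * r0_px + 1:
            raise SceneError("caps overlap at t = 0: spacing < initial diameter")
        y0 = (ny - span_y) / 2.0
        x0 = (nx - span_x) / 2.0
        centers = [(y0 + i * spacing_px, x0 + j * spacing_px)
                   for i in range(n_rows) for j in range(n_cols)]
        return np.array(centers[: self.n_caps])


@dataclass
class GroundTruth:
    """Per-cap, per-frame truth for a simulated movie.

    ``table`` columns: frame, time_s, cap_id, phase, area_um2 (analytic),
    mean_int (background-subtracted flat-top mean), sd_int, cy_um, cx_um,
    aspect, ecc. ``elongation_onset_frame`` is the first elongation frame.
    """

    table: pd.DataFrame
    elongation_onset_frame: int
    config: SceneConfig

    def cap(self, cap_id: int) -> pd.DataFrame:
        sub = self.table[self.table["cap_id"] == cap_id]
        if sub.empty:
            raise KeyError(f"no ground truth for cap {cap_id}")
        return sub.reset_index(drop=True)

    def fold_change(self, cap_id: int, t_start: float, t_end: float) -> float:
        sub = self.cap(cap_id)
        t = sub["time_s"].to_numpy()
        a = sub["area_um2"].to_numpy()
        return float(a[np.argmin(np.abs(t - t_end))] / a[np.argmin(np.abs(t - t_start))])


def _render_cap(canvas: np.ndarray, flat_accum: np.ndarray, center: tuple[float, float],
                area_px: float, aspect: float, amplitude: float,
                holes: list[tuple[float, float, float]] | None = None) -> np.ndarray:
    """Paint one flat-top elliptical cap onto ``canvas`` (adds ``amplitude``).

    Returns the boolean flat-top mask (profile == 1, holes excluded) and ORs
    it into ``flat_accum``.
    """
    ny, nx = canvas.shape
    r_px = math.sqrt(max(area_px, 1e-9) / math.pi)
    rx = r_px * math.sqrt(aspect)
    ry = r_px / math.sqrt(aspect)
    rg = math.sqrt(rx * ry)
    cy, cx = center
    pad = int(math.ceil(max(rx, ry) + 4 * EDGE_SIGMA_PX + 2))
    y_lo, y_hi = max(0, int(cy) - pad), min(ny, int(cy) + pad + 1)
    x_lo, x_hi = max(0, int(cx) - pad), min(nx, int(cx) + pad + 1)
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    u = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    e = (u - 1.0) * rg  # ~distance in px beyond the half-max contour
    prof = np.where(e <= -_HALF_WIDTH_PX, 1.0,
                    np.exp(-(e + _HALF_WIDTH_PX) ** 2 / (2.0 * EDGE_SIGMA_PX ** 2)))
    if holes:
        for hy, hx, hr in holes:
            prof[(yy - hy) ** 2 + (xx - hx) ** 2 <= hr ** 2] = 0.0
    canvas[y_lo:y_hi, x_lo:x_hi] += amplitude * prof
    flat_local = prof >= 1.0
    mask = np.zeros(canvas.shape, dtype=bool)
    mask[y_lo:y_hi, x_lo:x_hi] = flat_local
    flat_accum |= mask
    return mask


def simulate_cap_movie(config: SceneConfig) -> tuple[ImageStack4D, GroundTruth]:
    """Render a cap movie and its ground truth. Same seed => identical output."""
    config.validate()
    ny, nx = config.shape_yx
    ps = config.pixel_size_um
    rng = np.random.default_rng(config.seed)

    # frozen speckle fields, unit SD; the second one replaces the first at
    # fragmentation (scaled down) so heterogeneity drops when caps break up
    def _speckle():
        f = gaussian_filter(rng.standard_normal((ny, nx)), 1.0)
        return f / f.std()

    speckle_pre, speckle_frag = _speckle(), _speckle()

    centers0 = config._layout()
    drift_px = rng.normal(0.0, config.drift_sd_um / ps,
                          size=(config.n_caps, config.n_frames, 2)).cumsum(axis=1)
    drift_px[:, 0, :] = 0.0

    z_cap = config.apical_z + round(config.plane_offset_um / config.z_step_um)
    z_idx = np.arange(config.n_z)
    axial = np.exp(-((z_idx - z_cap) * config.z_step_um) ** 2
                   / (2.0 * config.axial_scale_um ** 2))
    axial[z_idx < config.apical_z] = 0.0

    frag_start = config.phase_starts_s["fragmentation"]
    movie = np.empty((config.n_frames, config.n_z, ny, nx), dtype=np.uint16)
    rows: list[dict] = []
    for f in range(config.n_frames):
        t = f * config.frame_interval_s
        plane = np.zeros((ny, nx))
        flat_all = np.zeros((ny, nx), dtype=bool)
        fragmenting = (config.phase_of(t) == "fragmentation"
                       and config.fragmentation_s > 0)
        speckle = speckle_frag if fragmenting else speckle_pre
        amp = config.het_amplitude * (config.het_frag_scale if fragmenting else 1.0)
        for c in range(config.n_caps):
            area_px = config.area_at(t) / ps ** 2
            aspect = config.aspect_at(t)
            cy, cx = centers0[c] + drift_px[c, f]
            holes = None
            if fragmenting and config.n_holes > 0:
                r_core = max(math.sqrt(area_px / math.pi) - _HALF_WIDTH_PX, 1.0)
                hole_pos = rng.uniform(-0.45 * r_core, 0.45 * r_core,
                                       size=(config.n_holes, 2))
                holes = [(cy + dy, cx + dx, config.hole_radius_px)
                         for dy, dx in hole_pos]
            flat = _render_cap(plane, flat_all, (cy, cx), area_px, aspect,
                               config.cap_intensity - config.background, holes)
            vals = (config.cap_intensity - config.background
                    + amp * speckle[flat]) if flat.any() else np.array([
                        config.cap_intensity - config.background])
            ecc = math.sqrt(max(1.0 - 1.0 / aspect ** 2, 0.0))
            rows.append({
                "frame": f, "time_s": t, "cap_id": c, "phase": config.phase_of(t),
                "area_um2": config.area_at(t),
                "mean_int": float(vals.mean()), "sd_int": float(vals.std()),
                "cy_um": cy * ps, "cx_um": cx * ps,
                "aspect": aspect, "ecc": ecc,
            })
        # speckle restricted to flat-top pixels so truth SD is controlled
        plane[flat_all] += amp * speckle[flat_all]

        vol = config.background + axial[:, None, None] * plane[None, :, :]
        if config.noise_sd > 0:
            vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape)
        movie[f] = np.clip(np.rint(vol), 0, 65535).astype(np.uint16)

    stack = ImageStack4D(movie, pixel_size_um=ps, z_step_um=config.z_step_um,
                         frame_interval_s=config.frame_interval_s, channel="F-actin")
    truth = GroundTruth(table=pd.DataFrame(rows),
                        elongation_onset_frame=config.elongation_onset_frame,
                        config=config)
    return stack, truth


def truth_track(truth: GroundTruth, cap_id: int) -> pd.DataFrame:
    """Ground truth for one cap as a measurement-style track table.

    Columns mirror the segmentation output (frame, area_um2, mean_int, sd_int,
    cy_um, cx_um, ecc) so dynamics operations can run directly on truth.
    """
    sub = truth.cap(cap_id)
    return sub[["frame", "area_um2", "mean_int", "sd_int", "cy_um", "cx_um",
                "ecc"]].copy()


# ---------------------------------------------------------------------------
# FRAP


@dataclass(frozen=True)
class FrapSimParams:
    """Ground-truth parameters of a simulated FRAP experiment.

    Defaults emulate a fast-turnover cortical actin cap: fast half-time 8.2 s
    (k_fast = ln2/8.2), ~19% immobile fraction, 1 s sampling over 60 s.
    """

    y0: float = 0.2                    # normalized intensity just after bleach
    y_minus1: float = 1.0              # normalized intensity 1 s before bleach
    plateau: float = 0.92
    pct_fast: float = 90.0
    k_fast: float = math.log(2.0) / 8.2
    k_slow: float = 0.01
    duration_s: float = 60.0
    interval_s: float = 1.0
    noise_sd: float = 0.0              # proportional noise on Y
    background: float = 50.0
    ref_drift_per_s: float = 0.5       # linear reference-cap intensity drift (AU/s)
    bleach_area_px: float = 400.0
    ref_area_px: tuple[float, ...] = (400.0, 380.0)
    ref_intensity: tuple[float, ...] = (800.0, 760.0)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.y0 <= self.plateau <= self.y_minus1:
            raise ParameterError("need 0 <= Y0 <= Plateau <= Y_-1")
        if not self.k_fast > self.k_slow > 0:
            raise ParameterError("need k_fast > k_slow > 0")
        if not 0.0 <= self.pct_fast <= 100.0:
            raise ParameterError("pct_fast must be in [0, 100]")
        if self.duration_s <= 0 or self.interval_s <= 0:
            raise ParameterError("duration and interval must be > 0")
        if len(self.ref_area_px) != len(self.ref_intensity) or not self.ref_area_px:
            raise ParameterError("need matching, non-empty reference areas/intensities")
        if self.noise_sd < 0 or self.background < 0:
            raise ParameterError("noise_sd and background must be >= 0")

    @property
    def immobile_fraction(self) -> float:
        """True immobile fraction, (Y_-1 - (Y0 + SpanFast)) / (Y_-1 - Y0)."""
        span_fast = (self.plateau - self.y0) * self.pct_fast * 0.01
        return (self.y_minus1 - (self.y0 + span_fast)) / (self.y_minus1 - self.y0)

    @property
    def t50_s(self) -> float:
        return math.log(2.0) / self.k_fast

    def curve(self, x) -> np.ndarray:
        return two_phase_association(x, self.y0, self.plateau, self.pct_fast,
                                     self.k_fast, self.k_slow)


def simulate_frap_experiment(params: FrapSimParams) -> tuple[FrapTrace, FrapSimParams]:
    """Embed an exact two-phase recovery into raw cap/reference/background series.

    The raw series are constructed so that applying the reference-cap
    normalization recovers the analytic Y(t) exactly (plus proportional noise
    when ``noise_sd`` > 0). The true parameters are returned alongside.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(math.floor(params.duration_s / params.interval_s + 1e-9)) + 1
    x = np.arange(n) * params.interval_s
    y = params.curve(x)
    if params.noise_sd > 0:
        y = y * (1.0 + rng.normal(0.0, params.noise_sd, size=n))

    times = np.concatenate([[-params.interval_s], x])
    y_all = np.concatenate([[params.y_minus1], y])

    refs_int = []
    for base in params.ref_intensity:
        refs_int.append(base + params.ref_drift_per_s * times)
    ref_products = [
        (ri - params.background) * area
        for ri, area in zip(refs_int, params.ref_area_px)
    ]
    denom = np.mean(ref_products, axis=0)
    if np.any(denom <= 0):
        raise SceneError("reference drift drove the normalization denominator <= 0")
    bleach_int = params.background + y_all * denom / params.bleach_area_px

    data = {"time_s": times, "bleach_int": bleach_int,
            "bleach_area": np.full_like(times, params.bleach_area_px)}
    for i, (ri, area) in enumerate(zip(refs_int, params.ref_area_px), start=1):
        data[f"ref{i}_int"] = ri
        data[f"ref{i}_area"] = np.full_like(times, area)
    data["background"] = np.full_like(times, params.background)
    return FrapTrace(pd.DataFrame(data)), params


# ---------------------------------------------------------------------------
# colocalization scenes


@dataclass(frozen=True)
class PunctumSpec:
    """One punctum pair: exact areas per channel, exact shared-pixel overlap."""

    area_a_um2: float
    area_b_um2: float
    shared_px: int
    intensity_a: float = 400.0
    intensity_b: float = 300.0


@dataclass(frozen=True)
class ColocSceneConfig:
    shape_yx: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    puncta: tuple[PunctumSpec, ...] = ()
    background_a: float = 50.0
    background_b: float = 40.0
    noise_sd: float = 0.0
    min_area_um2: float = 8.0          # analysis gate recorded in the truth table
    min_shared_px: int = 10            # colocalization rule recorded in the truth table
    seed: int = 0

    def validate(self) -> None:
        if not self.puncta:
            raise ParameterError("at least one punctum spec is required")
        for i, sp in enumerate(self.puncta):
            n_a = int(round(sp.area_a_um2 / self.pixel_size_um ** 2))
            n_b = int(round(sp.area_b_um2 / self.pixel_size_um ** 2))
            if sp.shared_px > min(n_a, n_b):
                raise SceneError(
                    f"punctum {i}: shared_px={sp.shared_px} exceeds the smaller "
                    f"channel area ({min(n_a, n_b)} px)")
            if sp.intensity_a <= self.background_a or sp.intensity_b <= self.background_b:
                raise ParameterError(f"punctum {i}: intensities must exceed background")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class ColocScene:
    channel_a: np.ndarray
    channel_b: np.ndarray
    labels_a: np.ndarray
    labels_b: np.ndarray
    truth: pd.DataFrame
    config: ColocSceneConfig


def _paint_pair(spec: PunctumSpec, center: tuple[int, int], ps: float,
                labels_a: np.ndarray, labels_b: np.ndarray, label: int) -> dict:
    """Paint one punctum pair with exact pixel counts and overlap."""
    ny, nx = labels_a.shape
    n_a = int(round(spec.area_a_um2 / ps ** 2))
    n_b = int(round(spec.area_b_um2 / ps ** 2))
    s = int(spec.shared_px)
    cy, cx = center
    r_a = math.sqrt(n_a / math.pi)
    pad = int(math.ceil(math.sqrt((n_a + n_b) / math.pi))) + 6
    y_lo, y_hi = cy - pad, cy + pad + 1
    x_lo, x_hi = cx - pad, cx + pad + 1
    if y_lo < 0 or x_lo < 0 or y_hi > ny or x_hi > nx:
        raise SceneError(f"punctum at {center} does not fit in the field")
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    coords = np.stack([yy.ravel(), xx.ravel()], axis=1)

    def _ordered(cy0, cx0):
        d2 = (coords[:, 0] - cy0) ** 2 + (coords[:, 1] - cx0) ** 2
        return coords[np.lexsort((coords[:, 1], coords[:, 0], d2))]

    a_pix = _ordered(cy, cx)[:n_a]
    if len(a_pix) < n_a:
        raise SceneError(f"punctum at {center}: window too small for area A")
    a_set = set(map(tuple, a_pix))

    # channel-B blob centered near A's right edge: take shared pixels from A,
    # the rest from outside A, both in order of distance to the B center
    b_pix, shared_got, out_got = [], 0, 0
    for p in map(tuple, _ordered(cy, cx + r_a)):
        in_a = p in a_set
        if in_a and shared_got < s:
            b_pix.append(p)
            shared_got += 1
        elif not in_a and out_got < n_b - s:
            b_pix.append(p)
            out_got += 1
        if shared_got == s and out_got == n_b - s:
            break
    else:
        raise SceneError(f"punctum at {center}: requested overlap is not constructible")

    ai = np.asarray(a_pix, dtype=int)
    bi = np.array(b_pix, dtype=int)
    labels_a[ai[:, 0], ai[:, 1]] = label
    labels_b[bi[:, 0], bi[:, 1]] = label
    return {"n_px_a": n_a, "n_px_b": n_b, "shared_px": s}


def simulate_coloc_scene(config: ColocSceneConfig) -> ColocScene:
    """Render a two-channel puncta scene with exact per-pair overlaps."""
    config.validate()
    ny, nx = config.shape_yx
    ps = config.pixel_size_um
    rng = np.random.default_rng(config.seed)

    n = len(config.puncta)
    max_px = max(max(round(sp.area_a_um2 / ps ** 2), round(sp.area_b_um2 / ps ** 2))
                 for sp in config.puncta)
    cell = 2 * (int(math.ceil(math.sqrt(2 * max_px / math.pi))) + 10)
    n_cols = max(nx // cell, 1)
    n_rows = math.ceil(n / n_cols)
    if n_rows * cell > ny:
        raise SceneError(
            f"field {ny}x{nx} px too small for {n} puncta of up to {max_px} px")

    labels_a = np.zeros((ny, nx), dtype=np.int32)
    labels_b = np.zeros((ny, nx), dtype=np.int32)
    rows = []
    for i, sp in enumerate(config.puncta):
        r, c = divmod(i, n_cols)
        center = (r * cell + cell // 2, c * cell + cell // 2)
        info = _paint_pair(sp, center, ps, labels_a, labels_b, i + 1)
        rows.append({
            "punctum_id": i + 1,
            "area_a_um2": info["n_px_a"] * ps ** 2,
            "area_b_um2": info["n_px_b"] * ps ** 2,
            "n_px_a": info["n_px_a"], "n_px_b": info["n_px_b"],
            "shared_px": info["shared_px"],
            "pass_gate_a": info["n_px_a"] * ps ** 2 > config.min_area_um2,
            "pass_gate_b": info["n_px_b"] * ps ** 2 > config.min_area_um2,
            "colocalized": info["shared_px"] >= config.min_shared_px,
            "intensity_ratio": (sp.intensity_a - config.background_a)
                               / (sp.intensity_b - config.background_b),
        })

    channel_a = np.full((ny, nx), config.background_a, dtype=float)
    channel_b = np.full((ny, nx), config.background_b, dtype=float)
    for i, sp in enumerate(config.puncta):
        channel_a[labels_a == i + 1] = sp.intensity_a
        channel_b[labels_b == i + 1] = sp.intensity_b
    if config.noise_sd > 0:
        channel_a += rng.normal(0.0, config.noise_sd, size=channel_a.shape)
        channel_b += rng.normal(0.0, config.noise_sd, size=channel_b.shape)
        np.clip(channel_a, 0.0, None, out=channel_a)
        np.clip(channel_b, 0.0, None, out=channel_b)

    return ColocScene(channel_a=channel_a, channel_b=channel_b,
                      labels_a=labels_a, labels_b=labels_b,
                      truth=pd.DataFrame(rows), config=config)


# ---------------------------------------------------------------------------
# fallout tables


@dataclass(frozen=True)
class FalloutSimConfig:
    """Linear fallout-rate vs. expansion-rate conditions with Gaussian noise."""

    n_conditions: int = 8
    intercept: float = 10.0            # fallout rate at zero expansion
    slope: float = -50.0               # fallout change per (um^2/s) of expansion
    noise_sd: float = 0.5
    rate_range: tuple[float, float] = (0.02, 0.16)
    intensity_intercept: float = 400.0
    intensity_slope: float = 2000.0    # mean cap intensity rises with expansion rate
    seed: int = 0

    def validate(self) -> None:
        if self.n_conditions < 3:
            raise ParameterError("n_conditions must be >= 3")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not self.rate_range[1] > self.rate_range[0]:
            raise ParameterError("rate_range must be increasing")


def simulate_fallout_dataset(config: FalloutSimConfig) -> pd.DataFrame:
    """Emit per-condition rows of expansion rate, mean intensity, fallout rate.

    Expansion rates are evenly spaced over ``rate_range``; fallout rate is
    ``intercept + slope * rate + eps`` with seeded Gaussian noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rates = np.linspace(*config.rate_range, config.n_conditions)
    eps = rng.normal(0.0, config.noise_sd, size=config.n_conditions) \
        if config.noise_sd > 0 else np.zeros(config.n_conditions)
    return pd.DataFrame({
        "condition": [f"cond_{i:02d}" for i in range(config.n_conditions)],
        "expansion_rate_um2_s": rates,
        "mean_intensity": config.intensity_intercept + config.intensity_slope * rates,
        "fallout_rate": config.intercept + config.slope * rates + eps,
    })
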