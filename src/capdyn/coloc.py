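"""Object-based colocalization and Costes-threshold Pearson correlation.

Mito-tag scoring rules: only puncta strictly larger than 8 um^2 are analyzed;
a punctum is called colocalized when it shares at least 10 pixels with a
partner in the other channel. Percent colocalization is the share of gated
puncta in the denominator channel (Arp3-positive compartments by default)
with such a partner. Recruitment ability is the background-corrected
GFP:mCherry intensity ratio inside a compartment, normalized to the same
ratio over a reference pixel pool (the gated mCherry-puncta pool by default).

Pixel-intensity colocalization uses the Costes automatic threshold: an
orthogonal (total least squares) regression B ~ m*A + c defines a family of
threshold pairs (T_A, m*T_A + c); T_A is lowered from the image maximum until
the Pearson correlation of the below-threshold pixels first reaches <= 0, and
the reported r is computed over the pixels above both thresholds. The
significance check shuffles PSF-sized blocks of channel A and reports the
fraction of randomized correlations at least as large as the observed one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ParameterError
from .segmentation import subtract_background, segment_caps

__all__ = [
    "detect_puncta", "call_colocalization", "recruitment_ability",
    "pearson_costes", "CostesResult",
]

# below this many above-threshold pixels a Pearson estimate is unstable;
# fall back to the full image and flag the thresholds degenerate
_MIN_ABOVE_PIXELS = 25


def detect_puncta(image: np.ndarray, pixel_size_um: float, *,
                  min_area_um2: float = 8.0, background_percentile: float = 5.0,
                  smooth_sigma_px: float = 0.0
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Detect puncta on a single plane and apply the strict area gate.

    Background subtraction, Otsu threshold, 8-connected components, then
    removal of objects with area <= ``min_area_um2`` (the gate is strict:
    8.10 um^2 passes, 7.90 um^2 and 8.00 um^2 do not). Returns the punctum
    table and the gated label map (deterministic labels, by descending area).
    """
    corrected, bg = subtract_background(np.asarray(image, float),
                                        percentile=background_percentile)
    labels = segment_caps(corrected, pixel_size_um, min_area_um2=0.0,
                          smooth_sigma_px=smooth_sigma_px)
    rows = []
    out = np.zeros_like(labels)
    new_id = 0
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        n_px = int(mask.sum())
        area = n_px * pixel_size_um ** 2
        if not area > min_area_um2:
            continue
        new_id += 1
        out[mask] = new_id
        ys, xs = np.nonzero(mask)
        rows.append({
            "punctum_id": new_id, "n_px": n_px, "area_um2": area,
            "mean_int": float(corrected[mask].mean()),
            "cy_px": float(ys.mean()), "cx_px": float(xs.mean()),
        })
    cols = ["punctum_id", "n_px", "area_um2", "mean_int", "cy_px", "cx_px"]
    return pd.DataFrame(rows, columns=cols), out


def call_colocalization(labels_a: np.ndarray, labels_b: np.ndarray, *,
                        min_shared_px: int = 10
                        ) -> tuple[pd.DataFrame, float]:
    """Object-based colocalization calls for the denominator channel A.

    Each A punctum is colocalized if some B punctum shares at least
    ``min_shared_px`` pixels with it. Returns the per-punctum table
    (id, best partner, shared pixels, flag) and the percent of A puncta
    colocalized. To score the opposite direction, swap the arguments.
    """
    if min_shared_px < 1:
        raise ParameterError("min_shared_px must be >= 1")
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ParameterError("label maps must have the same shape")

    both = (labels_a > 0) & (labels_b > 0)
    pair_counts: dict[tuple[int, int], int] = {}
    if both.any():
        pairs = np.stack([labels_a[both], labels_b[both]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        pair_counts = {(int(a), int(b)): int(c) for (a, b), c in zip(uniq, counts)}

    ids_a = [int(v) for v in np.unique(labels_a) if v > 0]
    rows = []
    for ida in ids_a:
        partners = {b: c for (a, b), c in pair_counts.items() if a == ida}
        if partners:
            best = max(partners, key=lambda b: (partners[b], -b))
            shared = partners[best]
        else:
            best, shared = 0, 0
        rows.append({"punctum_id": ida, "best_partner": best,
                     "shared_px": shared,
                     "colocalized": shared >= min_shared_px})
    table = pd.DataFrame(rows, columns=["punctum_id", "best_partner",
                                        "shared_px", "colocalized"])
    percent = 100.0 * table["colocalized"].mean() if len(table) else 0.0
    return table, float(percent)


def recruitment_ability(gfp: np.ndarray, mch: np.ndarray,
                        compartments: np.ndarray, reference_mask: np.ndarray, *,
                        gfp_background: float | None = None,
                        mch_background: float | None = None,
                        background_percentile: float = 5.0
                        ) -> tuple[pd.DataFrame, float]:
    """Normalized GFP:mCherry intensity ratio per compartment.

    Per compartment: (mean GFP - GFP background) / (mean mCh - mCh background),
    divided by the same ratio over ``reference_mask``. Backgrounds default to
    low-percentile estimates of each channel.
    """
    gfp = np.asarray(gfp, float)
    mch = np.asarray(mch, float)
    compartments = np.asarray(compartments)
    reference_mask = np.asarray(reference_mask, bool)
    if not reference_mask.any():
        raise ParameterError("reference region is empty")
    ids = [int(v) for v in np.unique(compartments) if v > 0]
    if not ids:
        raise ParameterError("no compartments to score")
    bg_g = float(np.percentile(gfp, background_percentile)) \
        if gfp_background is None else gfp_background
    bg_m = float(np.percentile(mch, background_percentile)) \
        if mch_background is None else mch_background

    ref_den = float(mch[reference_mask].mean() - bg_m)
    if ref_den <= 0:
        raise DegenerateDataError("reference mCherry signal does not exceed background")
    ref_ratio = float(gfp[reference_mask].mean() - bg_g) / ref_den
    if ref_ratio <= 0:
        raise DegenerateDataError("reference GFP:mCherry ratio is not positive")

    rows = []
    for ida in ids:
        mask = compartments == ida
        den = float(mch[mask].mean() - bg_m)
        if den <= 0:
            raise DegenerateDataError(
                f"compartment {ida}: mCherry signal does not exceed background")
        ratio = float(gfp[mask].mean() - bg_g) / den
        rows.append({"compartment_id": ida, "score": ratio / ref_ratio})
    table = pd.DataFrame(rows)
    return table, float(table["score"].mean())


# ---------------------------------------------------------------------------
# Costes


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    saa = float((a * a).sum())
    sbb = float((b * b).sum())
    if saa <= 0 or sbb <= 0:
        raise DegenerateDataError("Pearson undefined on constant data")
    return float((a * b).sum() / math.sqrt(saa * sbb))


def _tls_line(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Orthogonal (total least squares) regression b ~ m*a + c."""
    sxx = float(np.var(a))
    syy = float(np.var(b))
    sxy = float(np.mean((a - a.mean()) * (b - b.mean())))
    if sxx <= 0:
        raise DegenerateDataError("channel A is constant; Costes regression undefined")
    if abs(sxy) < 1e-30:
        m = math.sqrt(syy / sxx) if syy > 0 else 0.0
    else:
        m = (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)
    c = float(b.mean() - m * a.mean())
    return m, c


def _block_shuffle(img: np.ndarray, block: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffle non-overlapping block x block tiles; same-shape tiles permute
    among themselves (partial edge tiles form their own groups)."""
    ny, nx = img.shape
    tiles: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for y in range(0, ny, block):
        for x in range(0, nx, block):
            h = min(block, ny - y)
            w = min(block, nx - x)
            tiles.setdefault((h, w), []).append((y, x))
    out = np.empty_like(img)
    for (h, w), origins in tiles.items():
        perm = rng.permutation(len(origins))
        for src_i, dst_i in enumerate(perm):
            sy, sx = origins[src_i]
            dy, dx = origins[dst_i]
            out[dy:dy + h, dx:dx + w] = img[sy:sy + h, sx:sx + w]
    return out


@dataclass(frozen=True)
class CostesResult:
    r: float
    threshold_a: float
    threshold_b: float
    slope: float
    intercept: float
    randomized_r: np.ndarray
    randomization_fraction: float
    n_above: int
    thresholds_degenerate: bool
    search_path: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"r": self.r, "threshold_a": self.threshold_a,
                "threshold_b": self.threshold_b, "slope": self.slope,
                "intercept": self.intercept,
                "randomization_fraction": self.randomization_fraction,
                "n_above": self.n_above,
                "thresholds_degenerate": self.thresholds_degenerate,
                "randomized_r": list(map(float, self.randomized_r))}


def pearson_costes(img_a: np.ndarray, img_b: np.ndarray, *, psf_px: int = 3,
                   n_randomizations: int = 10, seed: int = 0,
                   n_steps: int = 256) -> CostesResult:
    """Costes-threshold Pearson correlation with block randomization.

    The threshold T_A descends linearly from max(A) in ``n_steps`` steps
    (T_B following the regression line); the search stops the first time the
    below-threshold Pearson correlation is <= 0 (or undefined). r is then
    computed over pixels above both thresholds; if fewer than 25 such pixels
    remain the full-image r is reported and the result flagged degenerate.
    """
    a = np.asarray(img_a, float).ravel()
    b = np.asarray(img_b, float).ravel()
    if img_a.shape != img_b.shape:
        raise ParameterError("images must have the same shape")
    if psf_px < 1 or n_randomizations < 1 or n_steps < 2:
        raise ParameterError("psf_px, n_randomizations and n_steps must be >= 1 (steps >= 2)")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("constant image; correlation undefined")

    m, c = _tls_line(a, b)
    t_grid = np.linspace(a.max(), a.min(), n_steps)
    path = []
    t_a = float(t_grid[0])
    stopped = False
    if m <= 0:
        # a non-positive regression slope means the channels carry no joint
        # positive signal; no threshold pair is meaningful (degenerate below)
        t_grid = np.empty(0)
        path.append(t_a)
        stopped = True
    for t in t_grid:
        path.append(float(t))
        t_a = float(t)
        below = (a < t) & (b < m * t + c)
        if below.sum() < 2:
            continue
        try:
            r_below = _pearson(a[below], b[below])
        except DegenerateDataError:
            continue
        if r_below <= 0:
            stopped = True
            break
    if not stopped:
        # never decorrelated: thresholds fall below the minimum, all pixels count
        t_a = float(a.min()) - 1e-12
    t_b = m * t_a + c

    above = (a > t_a) & (b > t_b)
    degenerate = int(above.sum()) < _MIN_ABOVE_PIXELS
    if not degenerate:
        try:
            r = _pearson(a[above], b[above])
            n_above = int(above.sum())
        except DegenerateDataError:  # above-threshold pixels constant in a channel
            degenerate = True
    if degenerate:
        r = _pearson(a, b)
        n_above = a.size

    rng = np.random.default_rng(seed)
    rand_rs = []
    for _ in range(n_randomizations):
        a_sh = _block_shuffle(np.asarray(img_a, float), psf_px, rng).ravel()
        if degenerate:
            rand_rs.append(_pearson(a_sh, b))
        else:
            sel = (a_sh > t_a) & (b > t_b)
            try:
                rand_rs.append(_pearson(a_sh[sel], b[sel])
                               if sel.sum() >= _MIN_ABOVE_PIXELS
                               else _pearson(a_sh, b))
            except DegenerateDataError:
                rand_rs.append(_pearson(a_sh, b))
    rand_rs = np.array(rand_rs)
    fraction = float(np.mean(rand_rs >= r))
    return CostesResult(r=float(r), threshold_a=t_a, threshold_b=float(t_b),
                        slope=float(m), intercept=float(c),
                        randomized_r=rand_rs, randomization_fraction=fraction,
                        n_above=n_above, thresholds_degenerate=bool(degenerate),
                        search_path=np.array(path))
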