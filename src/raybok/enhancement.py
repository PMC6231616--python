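"""Radiograph enhancement operators and input-preparation modes.

Four operators prepare a grayscale radiograph for annotation:

* **CLAHE** — contrast-limited adaptive histogram equalization.  The image is
  partitioned into a tile grid; each tile's 256-bin histogram is clipped at a
  fraction of the tile pixel count (the excess redistributed uniformly), its
  cumulative distribution scaled to the full output range forms the tile
  mapping, and every pixel is the bilinear interpolation of the mappings of
  its surrounding tile centers.
* **Non-local means** — each pixel becomes a weighted average over its search
  window, with weights decaying exponentially in the Gaussian-weighted mean
  squared difference between the surrounding patches.
* **Repetition padding** — rescale so the long side hits a fixed square size,
  then tile the image cyclically along the deficient axis.
* **Pseudo-RGB layering** — stack the original image with its CLAHE and
  NL-means renditions as three channels, so networks and feature extractors
  built for color input see complementary contrast information.

The six :data:`INPUT_MODES` combine these operators into the evaluated input
types.  Every operator consumes and produces intensities in [0, 1].  Each also
has a scikit-learn style transformer wrapper operating on lists of images, so
the enhancement stage composes with sklearn pipelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import correlate1d
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .images import check_gray, read_gray, write_image
from .irma import LabelTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClaheParams",
    "NlmParams",
    "PadParams",
    "INPUT_MODES",
    "apply_clahe",
    "apply_nl_means",
    "pad_with_repetition",
    "stack_layers",
    "prepare_input",
    "export_enhanced",
    "ClaheEnhancer",
    "NlMeansDenoiser",
    "RepetitionPadder",
    "RadiographPreparer",
]

#: The six evaluated input-preparation modes.
INPUT_MODES = ("original", "clahe", "nlmeans", "layered", "padded", "padded_layered")


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE parameters.

    ``clip_limit`` is a fraction of the tile pixel count (scale-free on the
    unit intensity range).  ``alpha`` shapes the target distribution and is
    inert for the default ``uniform`` shape.
    """

    num_tiles: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01
    n_bins: int = 256
    out_range: tuple[float, float] = (0.0, 1.0)
    distribution: str = "uniform"
    alpha: float = 0.4

    def __post_init__(self) -> None:
        if self.num_tiles[0] < 1 or self.num_tiles[1] < 1:
            raise ValueError("num_tiles must be >= 1 in each direction")
        if not (0.0 < self.clip_limit <= 1.0):
            raise ValueError("clip_limit must lie in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.distribution not in ("uniform", "rayleigh"):
            raise ValueError("distribution must be 'uniform' or 'rayleigh'")


@dataclass(frozen=True)
class NlmParams:
    """Non-local means parameters on the [0, 1] intensity scale.

    ``kernel_radius`` is the patch half-width (radius 4 gives 9x9 patches),
    ``window_radius`` the search-window half-width, and ``filter_strength``
    the exponential decay constant h.
    """

    kernel_radius: int = 4
    window_radius: int = 4
    filter_strength: float = 0.05

    def __post_init__(self) -> None:
        if self.kernel_radius < 1 or self.window_radius < 1:
            raise ValueError("radii must be >= 1")
        if self.filter_strength <= 0:
            raise ValueError("filter_strength must be > 0")


@dataclass(frozen=True)
class PadParams:
    """Repetition padding target: output is target_side x target_side."""

    target_side: int = 512

    def __post_init__(self) -> None:
        if self.target_side < 1:
            raise ValueError("target_side must be >= 1")


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def _tile_edges(n: int, tiles: int) -> np.ndarray:
    """Tile boundary indices: equal-size tiles, the last absorbing remainders."""
    base = n // tiles
    edges = np.arange(tiles + 1, dtype=np.int64) * base
    edges[-1] = n
    return edges

_MAX_REDISTRIBUTE_ITERS = 100


def clip_histogram(hist: np.ndarray, clip_count: float) -> np.ndarray:
    """Clip histogram bins at ``clip_count`` and redistribute the excess.

    The clipped excess is spread uniformly over all bins; because that can
    push bins over the limit again, redistribution iterates until the
    residual excess drops below one count, which is then spread uniformly
    without further clipping so total mass is conserved.
    """
    hist = np.asarray(hist, dtype=np.float64).copy()
    excess = float(np.maximum(hist - clip_count, 0.0).sum())
    np.minimum(hist, clip_count, out=hist)
    for _ in range(_MAX_REDISTRIBUTE_ITERS):
        if excess < 1.0:
            break
        hist += excess / hist.size
        new_excess = float(np.maximum(hist - clip_count, 0.0).sum())
        if new_excess >= excess:  # no capacity left; stop iterating
            np.minimum(hist, clip_count, out=hist)
            excess = new_excess
            break
        np.minimum(hist, clip_count, out=hist)
        excess = new_excess
    hist += excess / hist.size
    return hist


def _tile_mapping(tile: np.ndarray, params: ClaheParams) -> np.ndarray:
    """256-entry intensity mapping (bin index -> output value) for one tile."""
    nb = params.n_bins
    bins = np.minimum((tile * nb).astype(np.int64), nb - 1)
    hist = np.bincount(bins.ravel(), minlength=nb).astype(np.float64)
    npix = tile.size
    clip_count = math.ceil(params.clip_limit * npix)
    hist = clip_histogram(hist, clip_count)
    cdf = np.cumsum(hist) / npix
    lo, hi = params.out_range
    if params.distribution == "uniform":
        mapped = lo + cdf * (hi - lo)
    else:  # rayleigh-shaped target distribution
        cdf_safe = np.clip(cdf, 0.0, 1.0 - 1e-12)
        r = params.alpha * np.sqrt(-2.0 * np.log1p(-cdf_safe))
        r = r / max(float(r[-1]), 1e-12)
        mapped = lo + r * (hi - lo)
    return np.clip(mapped, min(lo, hi), max(lo, hi))


def apply_clahe(img: np.ndarray, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Pixels between four tile centers blend those tiles' mappings bilinearly;
    pixels outside the outer ring of centers replicate the nearest tile
    (clamped interpolation), so borders stay smooth.

    Raises
    ------
    ValueError
        If the image is smaller than the tile grid in either dimension.
    """
    img = check_gray(img)
    tr, tc = params.num_tiles
    H, W = img.shape
    if H < tr or W < tc:
        raise ValueError(
            f"image of shape {img.shape} is smaller than the {tr}x{tc} tile grid"
        )
    row_edges = _tile_edges(H, tr)
    col_edges = _tile_edges(W, tc)
    mappings = np.empty((tr, tc, params.n_bins), dtype=np.float64)
    for r in range(tr):
        for c in range(tc):
            tile = img[row_edges[r] : row_edges[r + 1], col_edges[c] : col_edges[c + 1]]
            mappings[r, c] = _tile_mapping(tile, params)

    centers_r = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:] - 1) / 2.0
    bins = np.minimum((img * params.n_bins).astype(np.int64), params.n_bins - 1)

    def _interp_coords(coords: np.ndarray, centers: np.ndarray):
        hi = np.searchsorted(centers, coords, side="left")
        lo = np.clip(hi - 1, 0, len(centers) - 1)
        hi = np.clip(hi, 0, len(centers) - 1)
        denom = centers[hi] - centers[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(denom > 0, (coords - centers[lo]) / np.where(denom > 0, denom, 1.0), 0.0)
        return lo, hi, np.clip(w, 0.0, 1.0)

    r_lo, r_hi, wy = _interp_coords(np.arange(H, dtype=np.float64), centers_r)
    c_lo, c_hi, wx = _interp_coords(np.arange(W, dtype=np.float64), centers_c)

    RL, RH = r_lo[:, None], r_hi[:, None]
    CL, CH = c_lo[None, :], c_hi[None, :]
    WY, WX = wy[:, None], wx[None, :]
    out = (
        (1 - WY) * (1 - WX) * mappings[RL, CL, bins]
        + (1 - WY) * WX * mappings[RL, CH, bins]
        + WY * (1 - WX) * mappings[RH, CL, bins]
        + WY * WX * mappings[RH, CH, bins]
    )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Non-local means
# ---------------------------------------------------------------------------

def _patch_kernel(radius: int) -> np.ndarray:
    """1-D Gaussian patch weights (sigma = radius / 2), normalized to sum 1."""
    off = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(off**2) / (2.0 * (radius / 2.0) ** 2))
    return g / g.sum()


def apply_nl_means(img: np.ndarray, params: NlmParams = NlmParams()) -> np.ndarray:
    """Non-local means denoising.

    For pixel *i* the output is ``sum_j w(i,j) v(j) / sum_j w(i,j)`` over the
    search window centred on *i* (clipped at the image border), with
    ``w(i,j) = exp(-d2(i,j) / h^2)`` where ``d2`` is the Gaussian-weighted
    mean squared difference between the two patches (patch weights sigma =
    kernel_radius / 2, normalized to sum 1).  Patches near the border are
    taken from the mirror-extended image.  The self weight ``w(i,i)`` is set
    to the maximum of the other weights in the window (1 when the window
    holds only *i*), the usual guard against the self-comparison dominating.
    """
    img = check_gray(img)
    R, Wr, h = params.kernel_radius, params.window_radius, params.filter_strength
    H, W = img.shape
    # Weights are symmetric, w(i, i+d) = w(i+d, i), so each offset pair
    # (d, -d) is computed once on a domain extended by the window radius and
    # accumulated in both directions.
    pad = R + 2 * Wr
    u = np.pad(img, pad, mode="symmetric")
    g = _patch_kernel(R)
    inv_h2 = 1.0 / (h * h)

    acc = np.zeros((H, W), dtype=np.float64)
    wsum = np.zeros((H, W), dtype=np.float64)
    wmax = np.zeros((H, W), dtype=np.float64)
    # A spans patch rows for centres in [-Wr, H+Wr)
    A = u[pad - Wr - R : pad + H + Wr + R, pad - Wr - R : pad + W + Wr + R]
    offsets = [
        (dy, dx)
        for dy in range(0, Wr + 1)
        for dx in range(-Wr, Wr + 1)
        if dy > 0 or dx > 0
    ]
    for dy, dx in offsets:
        B = u[
            pad - Wr - R + dy : pad + H + Wr + R + dy,
            pad - Wr - R + dx : pad + W + Wr + R + dx,
        ]
        d2 = (A - B) ** 2
        D = correlate1d(d2, g, axis=0, mode="constant")
        D = correlate1d(D, g, axis=1, mode="constant")
        D = D[R : R + H + 2 * Wr, R : R + W + 2 * Wr]  # patch centres [-Wr, H+Wr)
        w_full = np.exp(-D * inv_h2)
        vals = u[pad - Wr : pad + H + Wr, pad - Wr : pad + W + Wr]

        # forward: neighbour i+d, weight w_d(i); window members must be in-image
        w_f = w_full[Wr : Wr + H, Wr : Wr + W]
        v_f = vals[Wr + dy : Wr + dy + H, Wr + dx : Wr + dx + W]
        y0, y1 = max(0, -dy), min(H, H - dy)
        x0, x1 = max(0, -dx), min(W, W - dx)
        wm = np.zeros((H, W), dtype=np.float64)
        wm[y0:y1, x0:x1] = w_f[y0:y1, x0:x1]
        acc += wm * v_f
        wsum += wm
        np.maximum(wmax, wm, out=wmax)

        # backward: neighbour i-d, weight w_{-d}(i) = w_d(i-d)
        w_b = w_full[Wr - dy : Wr - dy + H, Wr - dx : Wr - dx + W]
        v_b = vals[Wr - dy : Wr - dy + H, Wr - dx : Wr - dx + W]
        y0, y1 = max(0, dy), min(H, H + dy)
        x0, x1 = max(0, dx), min(W, W + dx)
        wm = np.zeros((H, W), dtype=np.float64)
        wm[y0:y1, x0:x1] = w_b[y0:y1, x0:x1]
        acc += wm * v_b
        wsum += wm
        np.maximum(wmax, wm, out=wmax)

    wself = np.where(wmax > 0.0, wmax, 1.0)
    out = (acc + wself * img) / (wsum + wself)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Repetition padding
# ---------------------------------------------------------------------------

def pad_with_repetition(img: np.ndarray, params: PadParams = PadParams()) -> np.ndarray:
    """Pad to a square by cyclically repeating the image's own content.

    The image is first rescaled (bilinear, aspect ratio preserved) so its
    long side equals ``target_side``; the deficient axis is then filled with
    cyclic copies restarting from the first row/column, cropping the last
    copy.  Content is anchored top-left.  Already-square output is returned
    unchanged, which makes the operator idempotent.
    """
    img = check_gray(img)
    side = params.target_side
    H, W = img.shape
    if (H, W) == (side, side):
        return img.copy()
    scale = side / max(H, W)
    nh = side if H >= W else max(1, round(H * scale))
    nw = side if W >= H else max(1, round(W * scale))
    scaled = resize(img, (nh, nw), order=1, mode="edge", anti_aliasing=False,
                    preserve_range=True)
    scaled = np.clip(scaled, 0.0, 1.0)
    if nh < side:
        reps = -(-side // nh)
        scaled = np.tile(scaled, (reps, 1))[:side, :]
    if nw < side:
        reps = -(-side // nw)
        scaled = np.tile(scaled, (1, reps))[:, :side]
    return scaled


# ---------------------------------------------------------------------------
# Layering and mode dispatch
# ---------------------------------------------------------------------------

def stack_layers(
    original: np.ndarray, clahe_layer: np.ndarray, nlm_layer: np.ndarray
) -> np.ndarray:
    """Stack original/CLAHE/NL-means as the R/G/B channels of one image."""
    original = check_gray(original, "original")
    clahe_layer = check_gray(clahe_layer, "clahe_layer")
    nlm_layer = check_gray(nlm_layer, "nlm_layer")
    if not (original.shape == clahe_layer.shape == nlm_layer.shape):
        raise ValueError(
            f"layer shapes differ: {original.shape}, {clahe_layer.shape}, "
            f"{nlm_layer.shape}"
        )
    return np.stack([original, clahe_layer, nlm_layer], axis=-1)


def prepare_input(
    img: np.ndarray,
    mode: str,
    clahe: ClaheParams = ClaheParams(),
    nlm: NlmParams = NlmParams(),
    pad: PadParams = PadParams(),
) -> np.ndarray:
    """Prepare one radiograph according to an input mode.

    ``layered`` stacks the image with its CLAHE and NL-means renditions;
    ``padded_layered`` pads first and computes both enhancement layers on the
    padded image, keeping the CLAHE tile grid aligned with the final
    geometry.
    """
    if mode == "original":
        return check_gray(img).copy()
    if mode == "clahe":
        return apply_clahe(img, clahe)
    if mode == "nlmeans":
        return apply_nl_means(img, nlm)
    if mode == "layered":
        return stack_layers(img, apply_clahe(img, clahe), apply_nl_means(img, nlm))
    if mode == "padded":
        return pad_with_repetition(img, pad)
    if mode == "padded_layered":
        p = pad_with_repetition(img, pad)
        return stack_layers(p, apply_clahe(p, clahe), apply_nl_means(p, nlm))
    raise ValueError(f"unknown input mode {mode!r}; expected one of {INPUT_MODES}")


def export_enhanced(
    table: LabelTable,
    image_dir: str | Path,
    mode: str,
    out_dir: str | Path,
    clahe: ClaheParams = ClaheParams(),
    nlm: NlmParams = NlmParams(),
    pad: PadParams = PadParams(),
) -> dict:
    """Write enhanced copies of every image in ``table`` to ``out_dir``.

    Single-channel modes produce 8-bit grayscale PNGs, layered modes 24-bit
    RGB PNGs, filenames preserved.  Unreadable inputs are logged and skipped.
    Returns a manifest with the written and skipped filenames.
    """
    if mode not in INPUT_MODES:
        raise ValueError(f"unknown input mode {mode!r}; expected one of {INPUT_MODES}")
    image_dir, out_dir = Path(image_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    skipped: list[str] = []
    for image_id, _code in table:
        src = image_dir / image_id
        try:
            img = read_gray(src)
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable image %s: %s", src, exc)
            skipped.append(image_id)
            continue
        out = prepare_input(img, mode, clahe, nlm, pad)
        dest = out_dir / Path(image_id).with_suffix(".png").name
        write_image(out, dest)
        written.append(dest.name)
    return {"mode": mode, "count": len(written), "written": written, "skipped": skipped}


# ---------------------------------------------------------------------------
# scikit-learn transformer wrappers (operate on lists of images)
# ---------------------------------------------------------------------------

class _ImageListTransformer(BaseEstimator, TransformerMixin):
    """Stateless per-image transformer over lists of 2-D arrays."""

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X):
        return [self._transform_one(np.asarray(img)) for img in X]

    def _transform_one(self, img: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ClaheEnhancer(_ImageListTransformer):
    """CLAHE as a transformer; parameters mirror :class:`ClaheParams`."""

    def __init__(self, num_tiles=(8, 8), clip_limit=0.01, n_bins=256,
                 distribution="uniform", alpha=0.4):
        self.num_tiles = num_tiles
        self.clip_limit = clip_limit
        self.n_bins = n_bins
        self.distribution = distribution
        self.alpha = alpha

    def _params(self) -> ClaheParams:
        return ClaheParams(tuple(self.num_tiles), self.clip_limit, self.n_bins,
                           (0.0, 1.0), self.distribution, self.alpha)

    def _transform_one(self, img):
        return apply_clahe(img, self._params())


class NlMeansDenoiser(_ImageListTransformer):
    """Non-local means as a transformer; parameters mirror :class:`NlmParams`."""

    def __init__(self, kernel_radius=4, window_radius=4, filter_strength=0.05):
        self.kernel_radius = kernel_radius
        self.window_radius = window_radius
        self.filter_strength = filter_strength

    def _transform_one(self, img):
        return apply_nl_means(
            img, NlmParams(self.kernel_radius, self.window_radius, self.filter_strength)
        )


class RepetitionPadder(_ImageListTransformer):
    """Repetition padding as a transformer."""

    def __init__(self, target_side=512):
        self.target_side = target_side

    def _transform_one(self, img):
        return pad_with_repetition(img, PadParams(self.target_side))


class RadiographPreparer(_ImageListTransformer):
    """Full input-mode dispatch as a transformer (see :func:`prepare_input`)."""

    def __init__(self, mode="original", num_tiles=(8, 8), clip_limit=0.01,
                 n_bins=256, kernel_radius=4, window_radius=4,
                 filter_strength=0.05, target_side=512):
        self.mode = mode
        self.num_tiles = num_tiles
        self.clip_limit = clip_limit
        self.n_bins = n_bins
        self.kernel_radius = kernel_radius
        self.window_radius = window_radius
        self.filter_strength = filter_strength
        self.target_side = target_side

    def _transform_one(self, img):
        return prepare_input(
            img,
            self.mode,
            ClaheParams(tuple(self.num_tiles), self.clip_limit, self.n_bins),
            NlmParams(self.kernel_radius, self.window_radius, self.filter_strength),
            PadParams(self.target_side),
        )
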