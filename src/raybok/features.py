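"""Bag-of-Keypoints visual representation.

The representation chain is the classic bag-of-visual-words pipeline:

1. **Dense SIFT** — 128-dim gradient-orientation descriptors (4x4 spatial
   cells x 8 orientation bins) on a regular grid with 4-pixel spacing, at
   several cell sizes ("resolutions").
2. **Codebook** — k-means over a random sample of training descriptors
   (random-data-point init, at most 20 Lloyd iterations); cluster centers are
   the visual words, indexed by a kd-tree for L2 nearest-center lookup.
3. **Quantization + spatial histogram** — every descriptor maps to its
   nearest word; a 2x2 spatial grid of per-quadrant word histograms gives a
   4k-dim vector (4,000 at the default k = 1,000).
4. **PCA** — the histograms are reduced to 100 dimensions, fit on training
   data only.

:class:`BagOfKeypointsExtractor` wires the chain into a scikit-learn
transformer (``fit`` learns codebook + PCA, ``transform`` produces reduced
feature rows).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "DescriptorSet",
    "Codebook",
    "PcaModel",
    "dense_sift",
    "sample_descriptors",
    "build_codebook",
    "quantize",
    "spatial_histogram",
    "fit_pca",
    "apply_pca",
    "BagOfKeypointsExtractor",
]

N_ORIENTATIONS = 8
N_SPATIAL = 4  # 4x4 cell layout -> 128 dims
DESCRIPTOR_DIM = N_ORIENTATIONS * N_SPATIAL * N_SPATIAL
SIFT_CLAMP = 0.2


@dataclass
class DescriptorSet:
    """Dense SIFT frames and descriptors for one image.

    ``frames`` holds (x, y, scale) per descriptor — x/y are the patch-center
    coordinates in pixels, scale the spatial cell size.  Frames whose support
    has gradient energy below the contrast threshold are flagged low-contrast
    and carry zero descriptors.
    """

    frames: np.ndarray  # (n, 3) float: x, y, scale
    descriptors: np.ndarray  # (n, 128) float32
    low_contrast: np.ndarray  # (n,) bool
    image_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.descriptors):
            raise ValueError("frames and descriptors must have the same length")
        if self.descriptors.shape[1:] != (DESCRIPTOR_DIM,):
            raise ValueError(f"descriptors must be (n, {DESCRIPTOR_DIM})")
        if not np.all(np.isfinite(self.descriptors)):
            raise ValueError("descriptors contain non-finite values")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def valid_descriptors(self) -> np.ndarray:
        return self.descriptors[~self.low_contrast]

    @property
    def valid_frames(self) -> np.ndarray:
        return self.frames[~self.low_contrast]


def _orientation_maps(img: np.ndarray) -> np.ndarray:
    """Per-orientation gradient-magnitude maps with soft angular binning."""
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy).astype(np.float32)
    ang = (np.arctan2(gy, gx) % (2.0 * np.pi)).astype(np.float32)
    o = ang * np.float32(N_ORIENTATIONS / (2.0 * np.pi))
    o0 = np.floor(o).astype(np.int64) % N_ORIENTATIONS
    frac = o - np.floor(o)
    lo_w = mag * (np.float32(1.0) - frac)
    hi_w = mag * frac
    maps = np.zeros((N_ORIENTATIONS, *img.shape), dtype=np.float32)
    for b in range(N_ORIENTATIONS):
        maps[b] = lo_w * (o0 == b) + hi_w * ((o0 + 1) % N_ORIENTATIONS == b)
    return maps


def dense_sift(
    img: np.ndarray,
    step: int = 4,
    bin_sizes: Sequence[int] = (4, 6, 8, 10),
    contrast_threshold: float = 1e-4,
) -> DescriptorSet:
    """Dense SIFT descriptors on a regular grid at several cell sizes.

    For cell size *b* the descriptor support is ``4b x 4b`` pixels; frames are
    placed every ``step`` pixels wherever the support fits, giving
    ``floor((H - 4b)/step + 1) * floor((W - 4b)/step + 1)`` frames per scale.
    Descriptors are L2-normalized, clamped at 0.2, re-normalized, and finally
    stored on the conventional integer scale (value x 512 rounded, clipped at
    255) — the storage format of the classic SIFT implementations, which lets
    descriptors round-trip through uint8 losslessly.  A frame is flagged
    low-contrast (zero descriptor) when the mean gradient magnitude over its
    support falls below ``contrast_threshold``.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)  # layered input: collapse channels to luminance
    H, W = img.shape
    maps = np.moveaxis(_orientation_maps(img), 0, -1)  # (H, W, 8)
    # integral image (orientation-last) for O(1) box sums; float32 keeps the
    # memory traffic down and costs only ~1e-3 relative precision on the
    # normalized descriptors
    S = np.zeros((H + 1, W + 1, N_ORIENTATIONS), dtype=np.float32)
    np.cumsum(np.cumsum(maps, axis=0), axis=1, out=S[1:, 1:, :])

    frames_all, desc_all, flags_all = [], [], []
    for b in bin_sizes:
        support = N_SPATIAL * b
        if H < support or W < support:
            continue
        ny = (H - support) // step + 1
        nx = (W - support) // step + 1
        y0 = np.arange(ny) * step
        x0 = np.arange(nx) * step
        # box sum of every b x b cell anchored at (y, x)
        C = S[b:, b:] - S[:-b, b:] - S[b:, :-b] + S[:-b, :-b]
        raw = np.empty((ny, nx, N_SPATIAL, N_SPATIAL, N_ORIENTATIONS), dtype=np.float32)
        for i in range(N_SPATIAL):
            for j in range(N_SPATIAL):
                raw[:, :, i, j, :] = C[i * b :: step, j * b :: step][:ny, :nx]
        raw = raw.reshape(ny * nx, DESCRIPTOR_DIM)
        energy = raw.sum(axis=1) / (support * support)
        low = energy < contrast_threshold
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        desc = raw / norms
        np.minimum(desc, SIFT_CLAMP, out=desc)
        norms = np.linalg.norm(desc, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        desc /= norms
        np.rint(desc * 512.0, out=desc)
        np.minimum(desc, 255.0, out=desc)
        desc[low] = 0.0
        cx = (x0[None, :] + support / 2.0 - 0.5) + np.zeros((ny, 1))
        cy = (y0[:, None] + support / 2.0 - 0.5) + np.zeros((1, nx))
        frames = np.stack(
            [cx.ravel(), cy.ravel(), np.full(ny * nx, float(b))], axis=1
        )
        frames_all.append(frames)
        desc_all.append(desc.astype(np.float32))
        flags_all.append(low)

    if not frames_all:
        warnings.warn(
            f"image of shape {img.shape} is smaller than the smallest descriptor "
            f"support; returning an empty descriptor set",
            stacklevel=2,
        )
        return DescriptorSet(
            np.empty((0, 3)), np.empty((0, DESCRIPTOR_DIM), dtype=np.float32),
            np.empty(0, dtype=bool), (H, W),
        )
    return DescriptorSet(
        np.concatenate(frames_all),
        np.concatenate(desc_all),
        np.concatenate(flags_all),
        (H, W),
    )


def sample_descriptors(
    sets: Iterable[DescriptorSet] | DescriptorSet, n: int, seed: int
) -> np.ndarray:
    """Uniform sample without replacement from the pooled valid descriptors.

    Low-contrast descriptors never enter the pool.  Returns all available
    descriptors when fewer than ``n`` exist; raises when none do.
    """
    if isinstance(sets, DescriptorSet):
        sets = [sets]
    pools = [s.valid_descriptors for s in sets]
    pool = np.concatenate(pools) if pools else np.empty((0, DESCRIPTOR_DIM))
    if len(pool) == 0:
        raise ValueError("no valid (non-low-contrast) descriptors to sample from")
    rng = np.random.default_rng(seed)
    take = min(n, len(pool))
    idx = rng.choice(len(pool), size=take, replace=False)
    return pool[np.sort(idx)]


@dataclass
class Codebook:
    """k-means cluster centers plus a kd-tree index for L2 lookup."""

    centers: np.ndarray  # (k, 128)
    train_seed: int
    objective_history: list[float] = field(default_factory=list)
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @property
    def k(self) -> int:
        return len(self.centers)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.centers)
        return self._tree


def _assign_exact(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest-center assignment via the expanded-norm GEMM trick.

    Ties break toward the lowest center index (argmin convention).  Runs in
    float32 when both inputs are float32, float64 otherwise.
    Returns (labels, squared distances).
    """
    dt = np.float32 if (X.dtype == np.float32 and centers.dtype == np.float32) else np.float64
    Xf = X.astype(dt, copy=False)
    Cf = centers.astype(dt, copy=False)
    d2 = (
        (Xf * Xf).sum(axis=1, keepdims=True)
        - 2.0 * Xf @ Cf.T
        + (Cf * Cf).sum(axis=1)[None, :]
    )
    labels = np.argmin(d2, axis=1)
    dist2 = np.maximum(d2[np.arange(len(Xf)), labels], 0.0)
    return labels, dist2


def build_codebook(
    pool: np.ndarray,
    k: int,
    max_iter: int = 20,
    seed: int = 0,
    assign: str = "exact",
    approx_eps: float = 0.0,
) -> Codebook:
    """k-means codebook with random-data-point init and Lloyd iterations.

    ``assign='kdtree'`` routes nearest-center search through a kd-tree
    (``approx_eps > 0`` allows approximate pruning for speed; 0 keeps it
    exact, matching ``assign='exact'``).  Empty clusters are re-seeded from
    the points farthest from their current centers.  The within-cluster sum
    of squares after each assignment step is recorded in
    ``objective_history``.
    """
    pool = np.asarray(pool)
    if pool.dtype != np.float32:
        pool = pool.astype(np.float64)
    if pool.ndim != 2:
        raise ValueError("descriptor pool must be 2-D")
    n = len(pool)
    if n < k:
        raise ValueError(f"pool of {n} descriptors is smaller than k={k}")
    if assign not in ("exact", "kdtree"):
        raise ValueError("assign must be 'exact' or 'kdtree'")
    rng = np.random.default_rng(seed)
    centers = pool[rng.choice(n, size=k, replace=False)].copy()

    history: list[float] = []
    prev_labels: np.ndarray | None = None
    for _ in range(max_iter):
        if assign == "exact":
            labels, dist2 = _assign_exact(pool, centers)
        else:
            dist, labels = cKDTree(centers).query(pool, eps=approx_eps)
            dist2 = dist**2
        history.append(float(dist2.sum()))
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels
        counts = np.bincount(labels, minlength=k).astype(centers.dtype)
        onehot = sparse.csr_matrix(
            (np.ones(n, dtype=pool.dtype), labels, np.arange(n + 1)), shape=(n, k)
        )
        sums = onehot.T @ pool
        nonempty = counts > 0
        centers[nonempty] = sums[nonempty] / counts[nonempty, None]
        empty = np.flatnonzero(~nonempty)
        if len(empty) > 0:
            far = np.argsort(dist2)[::-1]
            for slot, idx in zip(empty, far):
                centers[slot] = pool[idx]
    return Codebook(centers=centers, train_seed=seed, objective_history=history)


def quantize(
    desc: DescriptorSet | np.ndarray, book: Codebook, mode: str = "exact"
) -> np.ndarray:
    """Map each valid descriptor to its nearest codebook word (L2).

    ``mode='exact'`` (default) uses brute-force distances with lowest-index
    tie-breaking — at moderate codebook sizes a single matrix product beats
    tree traversal in 128 dimensions; ``mode='kdtree'`` routes the lookup
    through the codebook's kd-tree index, worthwhile for large codebooks.
    Low-contrast frames are excluded (pair the result with
    ``desc.valid_frames``).
    """
    X = desc.valid_descriptors if isinstance(desc, DescriptorSet) else np.asarray(desc)
    if X.shape[1:] != (book.centers.shape[1],):
        raise ValueError(
            f"descriptor dim {X.shape[1:]} does not match codebook "
            f"dim {book.centers.shape[1]}"
        )
    if len(X) == 0:
        return np.empty(0, dtype=np.int64)
    if mode == "exact":
        labels, _ = _assign_exact(X, book.centers)
        return labels
    if mode == "kdtree":
        _, labels = book.tree.query(X)
        return np.asarray(labels, dtype=np.int64)
    raise ValueError("mode must be 'exact' or 'kdtree'")


def spatial_histogram(
    frames: np.ndarray,
    words: np.ndarray,
    image_size: tuple[int, int],
    k: int,
    grid: tuple[int, int] = (2, 2),
) -> np.ndarray:
    """Concatenated per-quadrant word histograms (row-major quadrant order).

    The image splits into ``grid`` equal cells; with odd sizes the extra
    pixels go to the right/bottom cells.  The result has length
    ``grid[0] * grid[1] * k`` and sums to the number of quantized frames.
    """
    frames = np.asarray(frames, dtype=np.float64)
    words = np.asarray(words, dtype=np.int64)
    if len(frames) != len(words):
        raise ValueError("frames and words must have the same length")
    if len(words) and (words.min() < 0 or words.max() >= k):
        raise ValueError(f"word ids must lie in [0, {k})")
    H, W = image_size
    gy, gx = grid
    if len(frames):
        qy = np.minimum(frames[:, 1] // max(H // gy, 1), gy - 1).astype(np.int64)
        qx = np.minimum(frames[:, 0] // max(W // gx, 1), gx - 1).astype(np.int64)
        flat = (qy * gx + qx) * k + words
    else:
        flat = np.empty(0, dtype=np.int64)
    return np.bincount(flat, minlength=gy * gx * k).astype(np.float64)


@dataclass
class PcaModel:
    """Principal-component reduction fit on training features only.

    Component signs are fixed (largest-magnitude loading positive) so the
    model is deterministic; ``explained_variances`` are the per-component
    score variances (ddof = 1), sorted descending.
    """

    mean: np.ndarray
    components: np.ndarray  # (out_dim, in_dim), row-orthonormal
    explained_variances: np.ndarray

    @property
    def out_dim(self) -> int:
        return len(self.components)


def fit_pca(train_features: np.ndarray, out_dim: int = 100) -> PcaModel:
    """Fit a PCA reduction of ``train_features`` to ``out_dim`` dimensions."""
    X = np.asarray(train_features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("train_features must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("train_features contain non-finite values")
    n = len(X)
    if n < out_dim + 1:
        raise ValueError(
            f"PCA to {out_dim} dims needs at least {out_dim + 1} training rows, "
            f"got {n}; reduce out_dim to at most {max(n - 1, 1)}"
        )
    pca = PCA(n_components=out_dim, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return PcaModel(
        mean=pca.mean_.copy(),
        components=components,
        explained_variances=pca.explained_variance_.copy(),
    )


def apply_pca(model: PcaModel, features: np.ndarray) -> np.ndarray:
    """Project (features - mean) onto the model's components."""
    X = np.asarray(features, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.components.shape[1]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match PCA input "
            f"dim {model.components.shape[1]}"
        )
    scores = (X - model.mean) @ model.components.T
    return scores[0] if single else scores


class BagOfKeypointsExtractor(BaseEstimator, TransformerMixin):
    """Dense-SIFT bag-of-keypoints features as a scikit-learn transformer.

    ``fit`` extracts dense SIFT from the training images, builds the k-means
    codebook from a per-image capped random sample of descriptors, computes
    the 2x2-grid word histograms of the training images and fits the PCA
    reduction on them — training data only, so no test-set leakage.
    ``transform`` maps any images to reduced feature rows.

    Parameters
    ----------
    k : codebook size (visual words).
    step, bin_sizes : dense-SIFT grid spacing and cell sizes.
    per_image_cap : descriptors each image may contribute to the clustering
        pool (the full set is still used for histograms).
    pca_dim : target dimensionality; clamped to ``min(pca_dim, n_train - 1,
        4k)`` for small training sets.
    assign : nearest-word search mode ('kdtree' or 'exact').
    """

    def __init__(
        self,
        k: int = 1000,
        step: int = 4,
        bin_sizes: tuple[int, ...] = (4, 6, 8, 10),
        per_image_cap: int = 1000,
        pca_dim: int = 100,
        kmeans_max_iter: int = 20,
        assign: str = "exact",
        contrast_threshold: float = 1e-4,
        grid: tuple[int, int] = (2, 2),
        normalize: bool = True,
        random_state: int = 0,
    ):
        self.k = k
        self.step = step
        self.bin_sizes = bin_sizes
        self.per_image_cap = per_image_cap
        self.pca_dim = pca_dim
        self.kmeans_max_iter = kmeans_max_iter
        self.assign = assign
        self.contrast_threshold = contrast_threshold
        self.grid = grid
        self.normalize = normalize
        self.random_state = random_state

    def _extract(self, img: np.ndarray) -> DescriptorSet:
        return dense_sift(
            img, step=self.step, bin_sizes=self.bin_sizes,
            contrast_threshold=self.contrast_threshold,
        )

    def _histogram(self, dset: DescriptorSet) -> np.ndarray:
        words = quantize(dset, self.codebook_, mode=self.assign)
        hist = spatial_histogram(
            dset.valid_frames, words, dset.image_shape, self.k, self.grid
        )
        if self.normalize and hist.sum() > 0:
            hist = hist / hist.sum()
        return hist

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        images = list(X)
        if not images:
            raise ValueError("need at least one training image")
        self.fit_checksum_ = _image_checksum(images)
        # single extraction pass: descriptors are integer-valued (0..255), so
        # they cache losslessly as uint8 until the codebook exists
        cached: list[tuple] = []
        pool_parts = []
        for i, img in enumerate(images):
            dset = self._extract(np.asarray(img))
            cached.append((dset.frames, dset.descriptors.astype(np.uint8),
                           dset.low_contrast, dset.image_shape))
            if dset.low_contrast.all():
                continue
            pool_parts.append(
                sample_descriptors(dset, self.per_image_cap,
                                   seed=(self.random_state * 7919 + i) % (2**31))
            )
        if not pool_parts:
            raise ValueError("all training descriptors are low-contrast")
        pool = np.concatenate(pool_parts)
        if len(pool) < self.k:
            raise ValueError(
                f"descriptor pool ({len(pool)}) smaller than codebook size k={self.k}"
            )
        self.codebook_ = build_codebook(
            pool, self.k, max_iter=self.kmeans_max_iter,
            seed=self.random_state % (2**31), assign=self.assign,
        )
        hists = np.stack([
            self._histogram(DescriptorSet(f, d.astype(np.float32), lc, shape))
            for f, d, lc, shape in cached
        ])
        del cached
        hist_dim = hists.shape[1]
        eff_dim = min(self.pca_dim, len(images) - 1, hist_dim)
        if eff_dim < 1:
            raise ValueError("too few training images to fit a PCA reduction")
        self.pca_ = fit_pca(hists, out_dim=eff_dim)
        self.n_features_out_ = eff_dim
        features = apply_pca(self.pca_, hists)
        self.train_features_ = features
        return features

    def transform(self, X):
        if not hasattr(self, "codebook_"):
            raise ValueError("extractor is not fitted")
        images = list(X)
        if not images:
            raise ValueError("need at least one image to transform")
        hists = np.stack([self._histogram(self._extract(np.asarray(im))) for im in images])
        return apply_pca(self.pca_, hists)


def _image_checksum(images: Sequence[np.ndarray]) -> str:
    """SHA-256 over the raw bytes of an image collection (fit provenance)."""
    h = hashlib.sha256()
    for img in images:
        arr = np.ascontiguousarray(np.asarray(img, dtype=np.float64))
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
    return h.hexdigest()
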