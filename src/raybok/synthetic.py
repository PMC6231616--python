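"""Synthetic radiograph-like images with multi-axial codes.

The generator renders grayscale phantoms whose class-discriminative factors
are wired one-to-one onto the four IRMA axes, so every pipeline stage is
exercisable without any external dataset:

* **A axis** (anatomy analogue) selects the foreground shape family —
  ellipse, elongated bar, compound blob, or ring;
* **D axis** (direction analogue) selects the in-plane rotation of the shape
  and of its interior texture;
* **T axis** (technique analogue) selects the global acquisition regime — a
  smooth rendition versus one overlaid with a fine concentric-ring texture
  (and a different foreground/background level pair);
* **B axis** (organ-system analogue) selects the interior texture pattern —
  directional stripes or a dot lattice — correlated with the shape it fills.

On top of the class factors each image gets a radial vignette, i.i.d.
Gaussian noise, and an aspect ratio sampled so both padding directions
occur.  All per-image randomness is a pure function of (code, seed), so
datasets are bit-reproducible.  A axis has the largest vocabulary (hardest
scheme) and T the smallest, mirroring the difficulty ordering of real
multi-axial annotation.  No anatomical realism is attempted.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import write_image
from .irma import IrmaCode, LabelTable

__all__ = ["GeneratorConfig", "generate_image", "generate_dataset", "stratified_split"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic dataset configuration.

    Vocabulary sizes default to 2 T x 3 D x 4 A x 2 B = 48 code combinations.
    Heights and widths are sampled independently from ``height_range`` /
    ``width_range`` so tall, wide, and near-square images all occur and
    repetition padding is exercised along both axes.
    """

    n_images: int = 300
    t_vocab: tuple[str, ...] = ("1121", "1124")
    d_vocab: tuple[str, ...] = ("127", "211", "410")
    a_vocab: tuple[str, ...] = ("500", "620", "732", "943")
    b_vocab: tuple[str, ...] = ("500", "625")
    height_range: tuple[int, int] = (200, 512)
    width_range: tuple[int, int] = (200, 512)
    noise_sigma: float = 0.05
    vignette_strength: float = 0.3
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("t_vocab", "d_vocab", "a_vocab", "b_vocab"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        for rng_ in (self.height_range, self.width_range):
            if rng_[0] < 64 or rng_[1] < rng_[0]:
                raise ValueError("size ranges must satisfy 64 <= lo <= hi")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def code_combinations(self) -> list[IrmaCode]:
        return [
            IrmaCode(t, d, a, b)
            for t, d, a, b in product(self.t_vocab, self.d_vocab,
                                      self.a_vocab, self.b_vocab)
        ]


def _code_rng(code: IrmaCode, seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(str(code).encode())])


# rotation angles per D slot; spacing chosen well above the renderer's
# interpolation tolerance so orientation is a clean class factor
_D_ANGLES_DEG = (0.0, 40.0, 80.0)


def _axis_index(value: str, vocab: tuple[str, ...], axis: str) -> int:
    try:
        return vocab.index(value)
    except ValueError:
        raise ValueError(f"{axis} axis value {value!r} not in vocabulary {vocab}") from None


def generate_image(code: IrmaCode, config: GeneratorConfig, seed: int) -> np.ndarray:
    """Render one phantom radiograph for ``code``; deterministic in (code, seed)."""
    ti = _axis_index(code.technical, config.t_vocab, "T")
    di = _axis_index(code.directional, config.d_vocab, "D")
    ai = _axis_index(code.anatomical, config.a_vocab, "A")
    bi = _axis_index(code.biological, config.b_vocab, "B")

    rng = _code_rng(code, seed)
    h = int(rng.integers(config.height_range[0], config.height_range[1] + 1))
    w = int(rng.integers(config.width_range[0], config.width_range[1] + 1))

    # isotropic coordinates centred on the image; unit = half the short side,
    # so rotation is a pure coordinate rotation regardless of aspect ratio
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    half = min(h, w) / 2.0
    x = (xx - (w - 1) / 2.0) / half
    y = (yy - (h - 1) / 2.0) / half

    theta = np.deg2rad(_D_ANGLES_DEG[di % len(_D_ANGLES_DEG)])
    xr = np.cos(theta) * x + np.sin(theta) * y
    yr = -np.sin(theta) * x + np.cos(theta) * y
    rho = np.hypot(x, y)

    # ----- A axis: shape family (binary mask, then softened) -----
    family = ai % 4
    if family == 0:  # one large ellipse
        mask = (xr / 0.78) ** 2 + (yr / 0.48) ** 2 <= 1.0
    elif family == 1:  # thin elongated bar
        mask = (np.abs(xr) <= 0.82) & (np.abs(yr) <= 0.16)
    elif family == 2:  # compound blob: three disjoint small ellipses
        m1 = ((xr - 0.42) / 0.22) ** 2 + ((yr - 0.24) / 0.18) ** 2 <= 1.0
        m2 = ((xr + 0.40) / 0.19) ** 2 + ((yr - 0.32) / 0.21) ** 2 <= 1.0
        m3 = (xr / 0.23) ** 2 + ((yr + 0.32) / 0.19) ** 2 <= 1.0
        mask = m1 | m2 | m3
    else:  # ring
        mask = (rho >= 0.38) & (rho <= 0.68)
    soft = gaussian_filter(mask.astype(np.float64), sigma=1.5)

    # ----- T axis: acquisition regime -----
    if ti % 2 == 0:
        bg, fg, ring_amp = 0.12, 0.82, 0.0
    else:
        bg, fg, ring_amp = 0.30, 0.62, 0.12

    # ----- B axis: interior texture pattern, oriented with the D rotation;
    # its spatial period tracks the A shape family (texture and anatomy are
    # correlated, as organ systems are with body regions) -----
    rho_px = rho * half
    period = (6.0, 9.0, 13.0, 18.0)[ai % 4]
    if bi % 2 == 0:  # directional stripes (sharpened to near-square-wave)
        tex = 0.22 * np.tanh(2.5 * np.sin(2.0 * np.pi * xr * half / period))
    else:  # dot lattice
        tex = 0.22 * np.tanh(
            2.5 * np.sin(2.0 * np.pi * xr * half / period)
            * np.sin(2.0 * np.pi * yr * half / period)
        )

    img = bg + (fg - bg) * soft + tex * soft
    if ring_amp > 0.0:
        img = img + ring_amp * np.sin(2.0 * np.pi * rho_px / 5.0)

    if config.vignette_strength > 0.0:
        rho_max = float(rho.max()) or 1.0
        img = img * (1.0 - config.vignette_strength * (rho / rho_max) ** 2)

    if config.noise_sigma > 0.0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def stratified_split(
    labels: list[str], test_fraction: float, seed: int
) -> list[str]:
    """Per-class 'train'/'test' flags; every class keeps at least one train row."""
    labels_arr = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    flags = np.array(["train"] * len(labels_arr), dtype=object)
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels_arr == cls)
        rng.shuffle(idx)
        n_test = min(int(round(test_fraction * len(idx))), len(idx) - 1)
        flags[idx[:n_test]] = "test"
    return list(flags)


def generate_dataset(
    config: GeneratorConfig, out_dir: str | Path
) -> tuple[Path, LabelTable]:
    """Write ``n_images`` phantom PNGs plus a label CSV with split flags.

    Codes cycle through all vocabulary combinations so class frequencies are
    balanced (within one image).  The train/test flag is an 80/20 split
    stratified by full IRMA label, never emptying a class's training side.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    combos = config.code_combinations()
    codes = [combos[i % len(combos)] for i in range(config.n_images)]
    order_rng = np.random.default_rng([config.seed, 0x5EED])
    order = order_rng.permutation(config.n_images)
    codes = [codes[i] for i in order]

    image_ids, written_codes = [], []
    for i, code in enumerate(codes):
        img = generate_image(code, config, seed=derive_image_seed(config.seed, i))
        name = f"synth_{i:05d}.png"
        write_image(img, out_dir / name)
        image_ids.append(name)
        written_codes.append(code)

    splits = stratified_split(
        [str(c) for c in written_codes], config.test_fraction,
        seed=(config.seed * 2654435761 + 17) % (2**31),
    )
    table = LabelTable(image_ids, written_codes, splits)
    table.to_csv(out_dir / "labels.csv")
    return out_dir, table


def derive_image_seed(base_seed: int, index: int) -> int:
    """Per-image seed derived from the dataset seed and image index."""
    return zlib.crc32(f"{base_seed}:{index}".encode()) & 0x7FFFFFFF
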