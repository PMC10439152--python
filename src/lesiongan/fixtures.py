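"""Image/mask I/O and a synthetic dermoscopy scene generator.

Real dermoscopy photographs are hard to segment because of low lesion/skin
contrast, colour variation, hair occlusion and acquisition artifacts such as
vignetting and sensor noise.  :func:`generate_scene` renders all of these
with known ground truth: a skin-tone background with a multiplicative
vignette and Gaussian noise, a single darker lesion whose boundary is an
ellipse-like blob with low-frequency radial perturbation, and a configurable
number of dark curved hair streaks drawn over the scene.  The mask records
the lesion region *before* hair occlusion, which is exactly what a human
annotator would label.

Everything is a pure function of ``(params, seed)``, so datasets regenerate
bit-identically and every downstream module is testable without downloads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from PIL import UnidentifiedImageError

from .errors import ContractError, FormatError, GenerationError

__all__ = [
    "SceneParams",
    "ManifestRecord",
    "DatasetManifest",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "resize_pair",
    "generate_scene",
    "generate_dataset",
]

MASK_THRESHOLD = 128  # 8-bit midpoint convention


# --------------------------------------------------------------------------
# parameters and manifests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic dermoscopy renderer.

    ``lesion_area_range`` is a fraction of image area; ``boundary_roughness``
    is the radial perturbation amplitude as a fraction of the lesion radius;
    ``contrast_delta`` is the mean-intensity gap between skin and lesion in
    [0, 1]; ``vignette_strength`` and ``noise_sd`` are in [0, 1] units of
    intensity.
    """

    image_size: int = 512
    lesion_area_range: tuple[float, float] = (0.05, 0.35)
    boundary_roughness: float = 0.15
    contrast_delta: float = 0.35
    hair_count: int = 3
    hair_width: float = 2.0
    vignette_strength: float = 0.25
    noise_sd: float = 0.03

    def __post_init__(self):
        lo, hi = self.lesion_area_range
        if not (0.0 < lo < hi < 1.0):
            raise ContractError("lesion_area_range must satisfy 0 < low < high < 1")
        if self.image_size < 8:
            raise ContractError("image_size must be at least 8 pixels")
        for name in ("boundary_roughness", "contrast_delta", "hair_width",
                     "vignette_strength", "noise_sd"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be nonnegative")
        if self.hair_count < 0:
            raise ContractError("hair_count must be >= 0")

    def with_size(self, size: int) -> "SceneParams":
        return replace(self, image_size=int(size))


@dataclass(frozen=True)
class ManifestRecord:
    image: str
    mask: str
    seed: int


@dataclass
class DatasetManifest:
    """Paths (relative to ``root``) and generation seeds of a dataset."""

    root: Path
    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def image_path(self, i: int) -> Path:
        return Path(self.root) / self.records[i].image

    def mask_path(self, i: int) -> Path:
        return Path(self.root) / self.records[i].mask

    def save(self, path: str | os.PathLike | None = None) -> Path:
        path = Path(path) if path is not None else Path(self.root) / "manifest.tsv"
        seeds = [r.seed for r in self.records]
        if len(set(seeds)) != len(seeds):
            raise ContractError("manifest seeds must be unique per record")
        for i in range(len(self.records)):
            for p in (self.image_path(i), self.mask_path(i)):
                if not p.exists():
                    raise FileNotFoundError(f"manifest entry missing on disk: {p}")
        lines = [f"{r.image}\t{r.mask}\t{r.seed}" for r in self.records]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DatasetManifest":
        path = Path(path)
        records = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            img, msk, seed = line.split("\t")
            records.append(ManifestRecord(img, msk, int(seed)))
        return cls(root=path.parent, records=records)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG as an H x W x 3 float array in [0, 1].

    Grayscale inputs are replicated to three channels; an alpha channel, if
    present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        with PILImage.open(path) as im:
            im.load()
            if im.mode not in ("RGB", "L"):
                im = im.convert("RGB") if im.mode not in ("I", "I;16", "F") else im.convert("L")
            arr = np.asarray(im)
    except UnidentifiedImageError as e:
        raise FormatError(f"not a readable image: {path}") from e
    arr = arr.astype(np.float32) / 255.0
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return arr


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write an H x W x 3 float image in [0, 1] as an 8-bit PNG/JPEG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ContractError(f"expected HxWx3 image, got shape {arr.shape}")
    data = np.round(arr * 255.0).astype(np.uint8)
    PILImage.fromarray(data, mode="RGB").save(Path(path))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel PNG as a binary H x W array.

    8-bit values >= 128 map to foreground (1).  Multi-channel files are
    accepted only when all channels agree.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    try:
        with PILImage.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except UnidentifiedImageError as e:
        raise FormatError(f"not a readable mask image: {path}") from e
    if arr.ndim == 3:
        channels = arr.reshape(arr.shape[0], arr.shape[1], -1)
        if not np.all(channels == channels[:, :, :1]):
            raise FormatError(f"multi-channel mask with unequal channels: {path}")
        arr = channels[:, :, 0]
    return (arr >= MASK_THRESHOLD).astype(np.uint8)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a binary H x W array as a single-channel 8-bit PNG (0/255)."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ContractError("mask must be strictly binary")
    PILImage.fromarray((arr * 255).astype(np.uint8), mode="L").save(Path(path))


def resize_pair(image: np.ndarray, mask: np.ndarray,
                target_size: int | tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Resize an image/mask pair: bilinear for the image, nearest for the mask.

    Nearest-neighbour keeps the mask strictly binary.
    """
    th, tw = (target_size, target_size) if np.isscalar(target_size) else tuple(target_size)
    if th < 1 or tw < 1:
        raise ContractError("target_size must be positive")
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ContractError(
            f"image spatial shape {image.shape[:2]} != mask shape {mask.shape}")
    if image.shape[:2] == (th, tw):
        return image.copy(), mask.astype(np.uint8).copy()
    chans = [
        np.asarray(
            PILImage.fromarray(image[:, :, c], mode="F").resize((tw, th), PILImage.BILINEAR)
        )
        for c in range(image.shape[2])
    ]
    rimg = np.clip(np.stack(chans, axis=2), 0.0, 1.0)
    rmask = np.asarray(
        PILImage.fromarray(mask.astype(np.uint8), mode="L").resize((tw, th), PILImage.NEAREST)
    )
    return rimg.astype(np.float32), rmask.astype(np.uint8)


# --------------------------------------------------------------------------
# synthetic scenes
# --------------------------------------------------------------------------

def _lesion_mask(rng: np.random.Generator, params: SceneParams,
                 yy: np.ndarray, xx: np.ndarray):
    """Sample one lesion; returns (binary mask, signed distance-like field)."""
    n = params.image_size
    cy, cx = rng.uniform(0.35, 0.65, size=2) * n
    area = rng.uniform(*params.lesion_area_range)
    # low-frequency radial perturbation: harmonics 2..6, 1/k spectrum,
    # normalized so the max deviation equals boundary_roughness
    ks = np.arange(2, 7)
    coeffs = rng.normal(size=(2, ks.size)) / ks
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    s = (coeffs[0] @ np.cos(np.outer(ks, theta.ravel()))
         + coeffs[1] @ np.sin(np.outer(ks, theta.ravel()))).reshape(theta.shape)
    smax = np.max(np.abs(s))
    if smax > 0:
        s = s / smax
    rho = 1.0 + params.boundary_roughness * s
    # radius correcting for E[rho^2] so the expected area matches the draw
    r0 = np.sqrt(area * n * n / (np.pi * max(np.mean(rho**2), 1e-6)))
    ecc = rng.uniform(0.75, 1.0)  # mild ellipticity
    d = np.hypot(dy * ecc, dx / ecc)
    fieldv = r0 * rho - d
    return fieldv >= 0.0, fieldv


def generate_scene(params: SceneParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic dermoscopy scene.

    Returns ``(image, mask)`` where the image is H x W x 3 in [0, 1] and the
    mask is the binary lesion region before hair occlusion.  Deterministic in
    ``(params, seed)``.  Raises :class:`GenerationError` if the lesion area
    constraint cannot be met after bounded retries.
    """
    n = params.image_size
    rng = np.random.default_rng(int(seed))
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    # skin tone: pinkish base with small per-image jitter; keep headroom for
    # the lesion contrast so the subtraction never clips
    base = np.array([0.06, -0.01, -0.05])
    mean_floor = min(0.95, params.contrast_delta + 0.12)
    skin_mean = rng.uniform(max(0.70, mean_floor), max(0.85, mean_floor + 0.02))
    jitter = rng.uniform(-0.04, 0.04, size=3)
    jitter -= jitter.mean()
    skin = np.clip(skin_mean + base + jitter, params.contrast_delta + 0.02, 1.0)

    lo, hi = params.lesion_area_range
    mask = fieldv = None
    for _ in range(24):
        m, f = _lesion_mask(rng, params, yy, xx)
        frac = m.mean()
        if lo <= frac <= hi:
            mask, fieldv = m, f
            break
    if mask is None:
        raise GenerationError(
            f"could not sample a lesion with area in [{lo}, {hi}] after 24 tries")

    lesion = skin - params.contrast_delta  # uniform per-channel gap
    alpha = np.clip(fieldv + 0.5, 0.0, 1.0)  # 1-px anti-aliased edge
    img = skin[None, None, :] + alpha[:, :, None] * (lesion - skin)[None, None, :]

    if params.vignette_strength > 0:
        ry = (yy - n / 2) / (n / 2)
        rx = (xx - n / 2) / (n / 2)
        img = img * (1.0 - params.vignette_strength * ((ry**2 + rx**2) / 2.0))[:, :, None]

    for _ in range(params.hair_count):
        p0 = rng.uniform(-0.1, 1.1, size=2) * n
        p1 = rng.uniform(0.1, 0.9, size=2) * n
        p2 = rng.uniform(-0.1, 1.1, size=2) * n
        shade = rng.uniform(0.05, 0.22)
        t = np.linspace(0.0, 1.0, 3 * n)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        radius = params.hair_width / 2.0
        w = int(np.ceil(radius)) + 1
        hair_alpha = np.zeros((n, n))
        for py, px in pts:
            iy, ix = int(round(py)), int(round(px))
            y0, y1 = max(iy - w, 0), min(iy + w + 1, n)
            x0, x1 = max(ix - w, 0), min(ix + w + 1, n)
            if y0 >= y1 or x0 >= x1:
                continue
            dd = np.hypot(yy[y0:y1, x0:x1] - py, xx[y0:y1, x0:x1] - px)
            a = np.clip(radius + 0.5 - dd, 0.0, 1.0)
            np.maximum(hair_alpha[y0:y1, x0:x1], a, out=hair_alpha[y0:y1, x0:x1])
        img = img * (1 - hair_alpha[:, :, None]) + shade * hair_alpha[:, :, None]

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)

    return np.clip(img, 0.0, 1.0).astype(np.float32), mask.astype(np.uint8)


def generate_dataset(n: int, params: SceneParams, master_seed: int,
                     outdir: str | os.PathLike) -> DatasetManifest:
    """Write ``n`` scene pairs as PNGs plus a TSV manifest.

    Per-record seeds derive deterministically from ``master_seed``, so the
    same call regenerates byte-identical files.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = (np.random.SeedSequence(int(master_seed)).generate_state(n) & 0x7FFFFFFF)
    # enforce uniqueness (collisions are astronomically unlikely, but cheap to fix)
    seen: set[int] = set()
    uniq = []
    for s in seeds.tolist():
        while s in seen:
            s = (s + 1) & 0x7FFFFFFF
        seen.add(s)
        uniq.append(s)
    records = []
    for i, s in enumerate(uniq):
        img, msk = generate_scene(params, s)
        iname, mname = f"img_{i:04d}.png", f"mask_{i:04d}.png"
        write_image(outdir / iname, img)
        write_mask(outdir / mname, msk)
        records.append(ManifestRecord(iname, mname, s))
    manifest = DatasetManifest(root=outdir, records=records)
    manifest.save()
    return manifest
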