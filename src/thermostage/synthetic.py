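"""Synthetic false-colour thermograms with known stage-dependent texture.

Each generated frame reproduces the visual structure the pipeline assumes:
a cool background, two smooth warm elliptical "thigh" regions seen from
behind, a vertical colour-scale bar on the right, pseudo-text strips along
the top and bottom, and — the severity signal — random hot/cold Gaussian
mottling blobs inside the thighs whose count and amplitude grow with the
Nuernberger-Mueller stage (the thermographic correlate of the clinical
"orange peel" appearance).  Stage 0 is perfectly smooth.

The scalar pseudo-temperature field is mapped through a rainbow palette by
default; rainbow luminance is deliberately non-monotone in the field value,
which stresses the grayscale conversion exactly the way real false-colour
exports do.  Ground-truth thigh masks are retrievable so ROI-extraction
recall is measurable.  Everything is deterministic given (stage, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import STAGES, DatasetManifest, RawThermogram, save_manifest, write_image

#: Piecewise-linear rainbow palette anchors (t, (r, g, b)) — blue through
#: cyan, green, yellow to red; luminance peaks mid-scale, not at the warm end.
_RAINBOW_ANCHORS = (
    (0.000, (0.00, 0.00, 0.50)),
    (0.125, (0.00, 0.00, 1.00)),
    (0.375, (0.00, 1.00, 1.00)),
    (0.625, (1.00, 1.00, 0.00)),
    (0.875, (1.00, 0.00, 0.00)),
    (1.000, (0.50, 0.00, 0.00)),
)


def apply_palette(field: np.ndarray, palette: str = "rainbow") -> np.ndarray:
    """Map a [0,1] scalar field to an (H, W, 3) uint8 false-colour raster."""
    t = np.clip(np.asarray(field, float), 0.0, 1.0)
    if palette == "grayscale":
        g = (t * 255).round().astype(np.uint8)
        return np.stack([g, g, g], axis=-1)
    if palette != "rainbow":
        raise ValueError(f"unknown palette {palette!r}")
    ts = [a[0] for a in _RAINBOW_ANCHORS]
    rgb = np.stack(
        [np.interp(t, ts, [a[1][c] for a in _RAINBOW_ANCHORS]) for c in range(3)],
        axis=-1,
    )
    return (rgb * 255).round().astype(np.uint8)


@dataclass(frozen=True)
class SynthConfig:
    """Layout and severity parameters of the synthetic thermograms.

    Counts/amplitudes of the mottling blobs (``blob_rate``,
    ``blob_amplitude``, indexed by stage) must be non-decreasing with zero
    at stage 0: healthy skin is smooth.  Amplitudes and ``base_contrast``
    are fractions of the unit dynamic range.
    """

    height: int = 240
    width: int = 320
    bar_width: int = 24
    bar_side: str = "right"
    text_strip_height: int = 16
    thigh_center_row_frac: float = 0.52
    thigh_center_col_fracs: tuple[float, float] = (0.32, 0.68)
    thigh_semi_axis_row: float = 75.0
    thigh_semi_axis_col: float = 48.0
    geometry_jitter: float = 0.04
    background_level: float = 0.25
    base_contrast: float = 0.4
    blob_rate: tuple[float, float, float, float] = (0.0, 6.0, 14.0, 26.0)
    blob_amplitude: tuple[float, float, float, float] = (0.0, 0.08, 0.14, 0.22)
    blob_radius: tuple[float, float] = (6.0, 14.0)
    noise_sd: float = 0.02
    palette: str = "rainbow"
    seed: int = 17

    def __post_init__(self):
        if np.any(np.diff(self.blob_rate) < 0) or np.any(np.diff(self.blob_amplitude) < 0):
            raise ValueError("blob rate and amplitude must be non-decreasing in stage")
        if self.blob_rate[0] != 0 or self.blob_amplitude[0] != 0:
            raise ValueError("stage 0 must be smooth: blob_rate[0] = amplitude[0] = 0")
        if self.blob_radius[1] >= min(self.thigh_semi_axis_row, self.thigh_semi_axis_col):
            raise ValueError("blob radius exceeds the thigh minor semi-axis")
        if self.bar_side not in ("left", "right"):
            raise ValueError("bar_side must be 'left' or 'right'")


def generate_thermogram(
    stage: int, config: SynthConfig = SynthConfig(), seed: int = 17
) -> tuple[RawThermogram, np.ndarray]:
    """One synthetic thermogram plus its ground-truth thigh mask.

    Returns ``(raw, mask)`` where ``raw.pixels`` is (H, W, 3) uint8 and
    ``mask`` is the boolean union of the two thigh ellipses.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    cfg = config
    rng = np.random.default_rng(seed)
    h, w = cfg.height, cfg.width
    rows, cols = np.mgrid[0:h, 0:w]

    content_w = w - cfg.bar_width
    col_off = cfg.bar_width if cfg.bar_side == "left" else 0

    field = np.full((h, w), cfg.background_level)
    mask = np.zeros((h, w), dtype=bool)
    jit = cfg.geometry_jitter
    for fcx in cfg.thigh_center_col_fracs:
        cy = cfg.thigh_center_row_frac * h * (1 + rng.uniform(-jit, jit))
        cx = col_off + fcx * content_w * (1 + rng.uniform(-jit, jit))
        ay = cfg.thigh_semi_axis_row * (1 + rng.uniform(-jit, jit))
        ax = cfg.thigh_semi_axis_col * (1 + rng.uniform(-jit, jit))
        r2 = ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2
        field += cfg.base_contrast * np.sqrt(np.clip(1.0 - r2, 0.0, None))
        mask |= r2 <= 1.0

    n_blobs = int(rng.poisson(cfg.blob_rate[stage]))
    amp = cfg.blob_amplitude[stage]
    if n_blobs > 0 and amp > 0 and mask.any():
        ys, xs = np.nonzero(mask)
        for _ in range(n_blobs):
            i = int(rng.integers(ys.size))
            by, bx = ys[i], xs[i]
            radius = rng.uniform(*cfg.blob_radius)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            sigma = radius / 2.0
            d2 = (rows - by) ** 2 + (cols - bx) ** 2
            field += sign * amp * np.exp(-d2 / (2.0 * sigma**2)) * mask

    field += rng.normal(0.0, cfg.noise_sd, size=(h, w))
    rgb = apply_palette(np.clip(field, 0.0, 1.0), cfg.palette)

    _composite_bar(rgb, cfg)
    _composite_text_strips(rgb, cfg, rng)

    raw = RawThermogram(
        pixels=rgb, source_id=f"synthetic_stage{stage}_seed{seed}", stage=stage
    )
    return raw, mask


def _composite_bar(rgb: np.ndarray, cfg: SynthConfig) -> None:
    h, w = rgb.shape[:2]
    sl = slice(0, cfg.bar_width) if cfg.bar_side == "left" else slice(w - cfg.bar_width, w)
    t = 1.0 - np.arange(h) / max(h - 1, 1)
    bar = apply_palette(np.tile(t[:, None], (1, cfg.bar_width)), cfg.palette)
    bar[::8, :, :] = 255               # dense tick/label lines of the scale
    bar[4::24, 2 : cfg.bar_width - 2 : 3, :] = 0   # pseudo numeric labels
    bar[:, 0] = bar[:, -1] = 255       # white frame
    rgb[:, sl, :] = bar


def _composite_text_strips(rgb: np.ndarray, cfg: SynthConfig, rng) -> None:
    """Pseudo-text: dark strips with small bright glyph-like rectangles."""
    h, w = rgb.shape[:2]
    th = cfg.text_strip_height
    for rows in (slice(0, th), slice(h - th, h)):
        rgb[rows, :, :] = 20
        for _ in range(60):
            r = int(rng.integers(2, max(th - 6, 3)))
            c = int(rng.integers(2, w - 6))
            gh = int(rng.integers(2, 6))
            gw = int(rng.integers(1, 4))
            rgb[rows][r : r + gh, c : c + gw, :] = 235


#: Per-stage image counts of the reference clinical database.
DEFAULT_COUNTS = {0: 27, 1: 93, 2: 61, 3: 31}


def generate_images(
    counts: dict[int, int] | None = None,
    config: SynthConfig = SynthConfig(),
    seed: int = 17,
) -> tuple[list[RawThermogram], list[np.ndarray]]:
    """Generate an in-memory labelled dataset: (thermograms, thigh masks).

    Per-image seeds are spawned deterministically from ``seed``; images come
    out grouped by stage in ascending stage order.
    """
    counts = DEFAULT_COUNTS if counts is None else counts
    total = sum(counts.get(s, 0) for s in STAGES)
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=total)
    raws, masks = [], []
    k = 0
    for s in STAGES:
        for _ in range(counts.get(s, 0)):
            raw, m = generate_thermogram(s, config, seed=int(child_seeds[k]))
            raw.source_id = f"im{k:04d}_stage{s}.png"
            raws.append(raw)
            masks.append(m)
            k += 1
    return raws, masks


def generate_dataset(
    counts: dict[int, int] | None = None,
    config: SynthConfig = SynthConfig(),
    seed: int = 17,
    out_dir=None,
    write_masks: bool = True,
) -> DatasetManifest:
    """Generate a labelled dataset and write it to ``out_dir`` as PNGs.

    File names follow the ``_stageK`` convention; ground-truth masks go to
    ``<name>_mask.png`` sidecars; a ``manifest.csv`` (``path,stage``) is
    written alongside.  Returns the manifest (paths relative to out_dir).
    """
    if out_dir is None:
        raise ValueError("out_dir is required; use generate_images() for in-memory data")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raws, masks = generate_images(counts, config, seed)
    entries = []
    for raw, m in zip(raws, masks):
        write_image(raw, out_dir / raw.source_id)
        if write_masks:
            mask_name = raw.source_id.replace(".png", "_mask.png")
            write_image(m.astype(np.uint8) * 255, out_dir / mask_name)
        entries.append((raw.source_id, raw.stage))
    manifest = DatasetManifest(entries=entries, name=out_dir.name)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
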