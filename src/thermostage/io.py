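"""Image and manifest I/O for the thermogram pipeline.

Thermograms arrive as ordinary 8-bit raster files (PNG/TIFF/JPEG), nominally
320x240 false-colour images straight off the camera software, with the
clinical severity stage (Nuernberger-Mueller scale, 0-3) encoded either in
the filename (token ``_stageK``) or in a CSV manifest with columns
``path,stage``.  A manifest label overrides a filename label.

All rasters are stored row-major with the origin at the top-left; every
coordinate in this package is 0-based and every interval half-open.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: Admissible Nuernberger-Mueller severity stages: 0 healthy, 1 mild,
#: 2 moderate (visible "orange peel" when standing), 3 severe.
STAGES = (0, 1, 2, 3)

STAGE_NAMES = {0: "healthy", 1: "mild", 2: "moderate", 3: "severe"}

_STAGE_TOKEN = re.compile(r"_stage([0-9])(?=[._]|$)")

_MIN_DIM = 64


class ThermogramIOError(IOError):
    """Unreadable or unsupported image/manifest file."""


class ManifestError(ValueError):
    """Malformed dataset manifest (bad label, duplicate path, ...)."""


def parse_stage(value) -> int:
    """Validate a stage label, returning it as a plain int in {0,1,2,3}."""
    try:
        stage = int(value)
    except (TypeError, ValueError):
        raise ManifestError(f"stage label {value!r} is not an integer")
    if stage not in STAGES:
        raise ManifestError(f"stage {stage} outside the admissible set {STAGES}")
    return stage


def stage_from_filename(path) -> int | None:
    """Extract a ``_stageK`` token from a file basename, if present."""
    m = _STAGE_TOKEN.search(Path(path).stem + "_")
    if m is None:
        return None
    k = int(m.group(1))
    return k if k in STAGES else None


@dataclass
class RawThermogram:
    """An as-acquired false-colour thermographic image.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W, 3)`` RGB or ``(H, W)`` grayscale, uint8 in [0, 255].
    source_id : str
        Provenance tag, usually the originating file name.
    stage : int or None
        Severity stage 0-3 if known.
    """

    pixels: np.ndarray
    source_id: str = ""
    stage: int | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(
                f"expected (H, W) or (H, W, 3) raster, got shape {px.shape}"
            )
        if px.shape[0] < _MIN_DIM or px.shape[1] < _MIN_DIM:
            raise ValueError(
                f"image {self.source_id!r} is {px.shape[0]}x{px.shape[1]}; "
                f"at least {_MIN_DIM}x{_MIN_DIM} required"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.stage is not None:
            self.stage = parse_stage(self.stage)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class DatasetManifest:
    """Ordered list of (image path, stage) pairs naming a labelled dataset."""

    entries: list[tuple[str, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        seen = set()
        checked = []
        for path, stage in self.entries:
            path = str(path)
            if path in seen:
                raise ManifestError(f"duplicate path in manifest: {path}")
            seen.add(path)
            checked.append((path, parse_stage(stage)))
        self.entries = checked

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def paths(self) -> list[str]:
        return [p for p, _ in self.entries]

    @property
    def stages(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=int)

    def class_counts(self) -> dict[int, int]:
        """Number of entries per stage, for all four stages (zeros included)."""
        counts = {s: 0 for s in STAGES}
        for _, s in self.entries:
            counts[s] += 1
        return counts

    def subset(self, indices, name: str = "") -> "DatasetManifest":
        return DatasetManifest(
            entries=[self.entries[i] for i in indices], name=name or self.name
        )


def read_image(path) -> RawThermogram:
    """Read a PNG/TIFF/JPEG raster into a :class:`RawThermogram`.

    The stage is populated from a ``_stageK`` filename token when present.
    JPEG input is accepted with a warning: lossy compression perturbs the
    gradient fields that downstream texture features rely on.
    """
    path = Path(path)
    if not path.exists():
        raise ThermogramIOError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            fmt = im.format
            if im.mode in ("I", "I;16", "F"):
                raise ThermogramIOError(
                    f"{path}: unsupported bit depth (mode {im.mode}); "
                    "8-bit per channel required"
                )
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if "A" in im.mode or im.mode == "P" else "L")
            pixels = np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ThermogramIOError(f"cannot decode image file {path}") from exc
    if fmt == "JPEG":
        logger.warning("%s: JPEG input; lossy artefacts may perturb gradients", path)
    return RawThermogram(
        pixels=pixels, source_id=path.name, stage=stage_from_filename(path)
    )


def write_image(image, path) -> None:
    """Write a raster (uint8 array, RawThermogram, or [0,1] float array) losslessly."""
    if isinstance(image, RawThermogram):
        px = image.pixels
    else:
        px = np.asarray(image)
        if px.dtype != np.uint8:
            px = (np.clip(px, 0.0, 1.0) * 255).round().astype(np.uint8)
    Image.fromarray(px).save(path)


def load_manifest(path, name: str = "") -> DatasetManifest:
    """Load a ``path,stage`` CSV manifest, preserving file order.

    Image paths are kept as written; relative paths are interpreted relative
    to the manifest's own directory by :func:`resolve_manifest_paths`.
    """
    path = Path(path)
    if not path.exists():
        raise ThermogramIOError(f"manifest not found: {path}")
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestError(f"{path}: empty file, expected 'path,stage' header")
        header = [h.strip().lower() for h in header]
        if header[:2] != ["path", "stage"]:
            raise ManifestError(
                f"{path}: expected header 'path,stage', got {','.join(header)}"
            )
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ManifestError(f"{path}:{i}: expected 2 columns, got {len(row)}")
            try:
                stage = parse_stage(row[1].strip())
            except ManifestError as exc:
                raise ManifestError(f"{path}:{i}: {exc}") from exc
            entries.append((row[0].strip(), stage))
    try:
        return DatasetManifest(entries=entries, name=name or path.stem)
    except ManifestError as exc:
        raise ManifestError(f"{path}: {exc}") from exc


def save_manifest(manifest: DatasetManifest, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "stage"])
        writer.writerows(manifest.entries)


def resolve_manifest_paths(manifest: DatasetManifest, root) -> DatasetManifest:
    """Return a copy with relative image paths anchored at `root`."""
    root = Path(root)
    entries = []
    for p, s in manifest.entries:
        q = Path(p)
        entries.append((str(q if q.is_absolute() else root / q), s))
    return DatasetManifest(entries=entries, name=manifest.name)
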