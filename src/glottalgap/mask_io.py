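"""Reading, writing and preprocessing of labeled vocal-fold mask sequences.

A recording is a sequence of per-frame label grids with four region codes:
0 = background, 1 = left vocal fold, 2 = right vocal fold, 3 = glottis.
Frames use a mathematical coordinate convention with the origin at the
lower-left corner: pixel ``(col=i, row-from-bottom=j)`` spans the unit
square ``[i, i+1) x [j, j+1)``, so a continuous point ``(x, y)`` belongs to
the cell ``(floor(x), floor(y))``.  Internally label grids are stored as
``labels[j, i]`` with row 0 at the *bottom* of the image; the PNG codecs
flip vertically on the way in and out, since raster images put row 0 at
the top.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

BACKGROUND, LEFT_FOLD, RIGHT_FOLD, GLOTTIS = 0, 1, 2, 3
LABELS = (BACKGROUND, LEFT_FOLD, RIGHT_FOLD, GLOTTIS)

#: Default visualization palette: left fold blue, right fold yellow,
#: glottis teal, background black.
DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    BACKGROUND: (0, 0, 0),
    LEFT_FOLD: (0, 0, 255),
    RIGHT_FOLD: (255, 255, 0),
    GLOTTIS: (0, 128, 128),
}

MIN_DIM = 8

GROUPS = ("normal", "gap", "unknown")


class MaskIOError(ValueError):
    """Raised for malformed mask inputs (unmapped colors, bad dimensions...)."""


@dataclass
class LabeledFrame:
    """One 2D grid of region labels.

    ``labels[j, i]`` is the code of the pixel in column ``i``, row ``j``
    counted from the bottom of the image.
    """

    labels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise MaskIOError("label grid must be 2D")
        h, w = self.labels.shape
        if h < MIN_DIM or w < MIN_DIM:
            raise MaskIOError(
                f"label grid must be at least {MIN_DIM}x{MIN_DIM}, got {h}x{w}"
            )
        if self.labels.max(initial=0) > GLOTTIS:
            bad = sorted(set(np.unique(self.labels)) - set(LABELS))
            raise MaskIOError(f"unknown label codes {bad}")
        if self.frame_index < 0:
            raise MaskIOError("frame_index must be >= 0")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def label_at(self, x: float, y: float) -> int:
        """Region code of the pixel cell containing continuous point (x, y).

        Points outside the frame are background.
        """
        i, j = int(np.floor(x)), int(np.floor(y))
        if 0 <= i < self.width and 0 <= j < self.height:
            return int(self.labels[j, i])
        return BACKGROUND


@dataclass
class MaskSequence:
    """An ordered recording of labeled frames with acquisition metadata.

    ``meta`` carries optional provenance such as a simulator's ground truth;
    it is not interpreted by the measurement code.
    """

    frames: list[LabeledFrame]
    fps: float = 4000.0
    subject_id: str = "unknown"
    group: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise MaskIOError("fps must be > 0")
        if self.group not in GROUPS:
            raise MaskIOError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.frames:
            shape = self.frames[0].labels.shape
            for k, fr in enumerate(self.frames):
                if fr.labels.shape != shape:
                    raise MaskIOError(
                        f"non-uniform frame dimensions: frame {k} is "
                        f"{fr.labels.shape}, expected {shape}"
                    )
                if fr.frame_index != k:
                    raise MaskIOError("frame_index must increase 0,1,2,...")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class GrayFrame:
    """A single-channel (or multi-channel) intensity frame in [0, 255]."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        self.intensities = np.clip(arr, 0.0, 255.0)


def gamma_correct(frame: GrayFrame, gamma: float) -> GrayFrame:
    """Apply a power-law intensity mapping v -> round(255 * (v/255)^gamma).

    Used to match recordings whose camera gamma differs from the one a
    downstream segmentation network was trained on.  Applied per channel
    for multi-channel input; monotone in v for any fixed gamma > 0.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    v = np.asarray(frame.intensities, dtype=float)
    out = np.round(255.0 * (v / 255.0) ** gamma)
    return GrayFrame(np.clip(out, 0.0, 255.0))


# ---------------------------------------------------------------------------
# PNG sequence I/O


def _natural_key(name: str) -> list:
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def _palette_lut(palette: Mapping[int, tuple[int, int, int]]) -> dict[tuple, int]:
    lut = {}
    for code, rgb in palette.items():
        if code not in LABELS:
            raise MaskIOError(f"palette maps unknown code {code}")
        lut[tuple(int(c) for c in rgb)] = int(code)
    return lut


def write_mask_sequence(
    seq: MaskSequence,
    path: str | Path,
    palette: Mapping[int, tuple[int, int, int]] = DEFAULT_PALETTE,
) -> list[Path]:
    """Write one indexed PNG per frame plus a JSON metadata sidecar.

    Encoding is lossless; ``read_mask_sequence`` on the result restores
    label grids cell for cell.  Returns the written image paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    flat_palette = []
    for code in LABELS:
        flat_palette.extend(palette[code])
    written = []
    for fr in seq.frames:
        # flip: internal row 0 is the image bottom, PNG row 0 is the top
        img = Image.fromarray(np.flipud(fr.labels), mode="P")
        img.putpalette(flat_palette)
        out = path / f"frame_{fr.frame_index:05d}.png"
        img.save(out, format="PNG")
        written.append(out)
    meta = {"fps": seq.fps, "subject_id": seq.subject_id, "group": seq.group}
    (path / "sequence.json").write_text(json.dumps(meta, indent=2))
    return written


def read_mask_sequence(
    path: str | Path,
    palette: Mapping[int, tuple[int, int, int]] = DEFAULT_PALETTE,
    fps: float | None = None,
    subject_id: str | None = None,
    group: str | None = None,
) -> MaskSequence:
    """Read a directory of per-frame mask images into a MaskSequence.

    Frames are ordered by natural sort of filenames.  Colors absent from
    the palette raise ``MaskIOError`` — an unmapped label color is a wrong
    palette, never silently background.  Metadata comes from the
    ``sequence.json`` sidecar when present; explicit arguments override it.
    """
    path = Path(path)
    if not path.exists():
        raise MaskIOError(f"no such path: {path}")
    if not path.is_dir():
        raise MaskIOError(f"expected a directory of mask images: {path}")
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}),
        key=lambda p: _natural_key(p.name),
    )
    jpegs = [p for p in files if p.suffix.lower() in {".jpg", ".jpeg"}]
    if jpegs:
        raise MaskIOError(
            f"JPEG masks are rejected (lossy compression corrupts labels): {jpegs[0].name}"
        )
    if not files:
        raise MaskIOError(f"empty directory, no mask images found in {path}")

    lut = _palette_lut(palette)
    frames = []
    for k, f in enumerate(files):
        rgb = np.asarray(Image.open(f).convert("RGB"))
        colors, inverse = np.unique(rgb.reshape(-1, 3), axis=0, return_inverse=True)
        codes = np.empty(len(colors), dtype=np.uint8)
        for ci, col in enumerate(colors):
            key = tuple(int(c) for c in col)
            if key not in lut:
                raise MaskIOError(f"unmapped label color {key} in {f.name}")
            codes[ci] = lut[key]
        labels = codes[inverse].reshape(rgb.shape[:2])
        frames.append(LabeledFrame(np.flipud(labels), frame_index=k))

    meta = {}
    sidecar = path / "sequence.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return MaskSequence(
        frames,
        fps=fps if fps is not None else float(meta.get("fps", 4000.0)),
        subject_id=subject_id
        if subject_id is not None
        else str(meta.get("subject_id", path.name)),
        group=group if group is not None else str(meta.get("group", "unknown")),
    )
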