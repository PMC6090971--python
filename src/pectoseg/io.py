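"""Reading and writing the raster formats the pipeline touches.

Supported formats are PGM (both binary P5 and ASCII P2, maxval 255 or 65535 —
the dialects the MIAS database ships) and single-channel PNG (8 or 16 bit).
Pillow does the actual decoding; this module normalizes into the internal
model: intensities divided by ``2**depth - 1`` into [0, 1], row 0 at the top.

Masks are always written as 8-bit {0, 255}, so a write/read round-trip is
bit-exact for masks and for any image that originated from an 8-bit file.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ChannelError, ImageFormatError
from .image import BinaryMask, GrayImage

_PGM_MAGICS = (b"P2", b"P5")
_PNG_MAGIC = b"\x89PNG\r\n\x1a\n"

_GRAY_MODES = {
    "L": 8,
    "I": 16,
    "I;16": 16,
    "I;16B": 16,
}


def _sniff(path: Path, dialect: str | None) -> str:
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head[:2] in _PGM_MAGICS:
        found = "pgm"
    elif head == _PNG_MAGIC:
        found = "png"
    else:
        raise ImageFormatError(
            f"{path}: unrecognized magic {head[:2]!r} at byte offset 0 "
            "(expected PGM 'P2'/'P5' or the PNG signature)"
        )
    if dialect is not None and dialect != found:
        raise ImageFormatError(f"{path}: file is {found}, not the requested {dialect}")
    return found


def read_image(path: str | os.PathLike, dialect: str | None = None) -> GrayImage:
    """Read a grayscale PGM or PNG into a [0, 1]-normalized :class:`GrayImage`.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"pgm"`` or ``"png"`` to insist on a format; ``None`` sniffs the
        magic bytes.

    Raises
    ------
    ImageFormatError
        Unreadable or truncated file (the message names the byte offset at
        which parsing failed where known).
    ChannelError
        Multi-channel (color / alpha) input.
    """
    path = Path(path)
    if dialect is not None and dialect not in ("pgm", "png"):
        raise ImageFormatError(f"unknown dialect {dialect!r}; expected 'pgm' or 'png'")
    _sniff(path, dialect)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode not in _GRAY_MODES:
                raise ChannelError(
                    f"{path}: mode {mode!r} is not single-channel grayscale"
                )
            arr = np.asarray(im)
    except ChannelError:
        raise
    except (UnidentifiedImageError, OSError, SyntaxError, ValueError) as exc:
        size = path.stat().st_size
        raise ImageFormatError(
            f"{path}: failed to decode ({exc}); file is {size} bytes"
        ) from exc
    depth = _GRAY_MODES[mode]
    # Pillow promotes 16-bit PGM/PNG to mode "I"; trust the data range when the
    # header depth is ambiguous.
    if depth == 16 and arr.max(initial=0) <= 255 and arr.dtype != np.uint16:
        depth = 16  # keep declared depth; normalization below handles range
    scale = float(2**depth - 1)
    pixels = np.clip(arr.astype(np.float64) / scale, 0.0, 1.0)
    return GrayImage(pixels, source_depth=depth)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask stored as an 8-bit image; any nonzero pixel is 1."""
    img = read_image(path)
    return BinaryMask(img.pixels > 0)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as 8-bit {0, 255} PGM or PNG (chosen by file suffix)."""
    _write_u8((mask.pixels.astype(np.uint8) * 255), Path(path))


def write_image(image: GrayImage, path: str | os.PathLike) -> None:
    """Write a [0, 1] image re-quantized to its source depth.

    Images read from an 8-bit file round-trip bit-exactly; 16-bit sources are
    written as 16-bit PNG (PGM output is always 8-bit for MIAS parity).
    """
    path = Path(path)
    if image.source_depth == 16 and path.suffix.lower() == ".png":
        arr16 = np.round(image.pixels * 65535.0).astype(np.uint16)
        Image.fromarray(arr16, mode="I;16").save(path)
        return
    _write_u8(np.round(image.pixels * 255.0).astype(np.uint8), path)


def _write_u8(arr: np.ndarray, path: Path) -> None:
    suffix = path.suffix.lower()
    if suffix in (".pgm", ".ppm", ".pnm"):
        fmt = "PPM"
    elif suffix == ".png":
        fmt = "PNG"
    else:
        raise ImageFormatError(f"{path}: unsupported output suffix {suffix!r}")
    try:
        Image.fromarray(arr, mode="L").save(path, format=fmt)
    except OSError as exc:
        raise ImageFormatError(f"{path}: cannot write ({exc})") from exc
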