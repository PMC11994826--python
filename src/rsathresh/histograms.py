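"""Image loading, channel splitting and 256-bin intensity histograms.

Images are plain ``numpy.ndarray`` buffers of dtype ``uint8``: a 2-D array
``(M, Q)`` for grayscale, a 3-D array ``(M, Q, 3)`` for RGB.  All downstream
code works on the per-channel histogram, i.e. the empirical probability
``p_i = f_i / N`` of each of the ``L = 256`` gray levels, where ``f_i`` is
the number of pixels at level ``i`` and ``N = M·Q`` the pixel count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Number of gray levels; the whole pipeline assumes 8-bit images.
N_LEVELS = 256

CHANNEL_NAMES = ("R", "G", "B")


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid 8-bit image buffer and return it.

    Accepts 2-D grayscale or 3-D RGB arrays with intensities in [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3):
        raise ValueError(f"image must be 2-D or 3-D, got shape {arr.shape}")
    if arr.ndim == 3 and arr.shape[2] != 3:
        raise ValueError(f"color image must have 3 channels, got {arr.shape[2]}")
    if arr.size == 0:
        raise ValueError("image must contain at least one pixel")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) or np.issubdtype(arr.dtype, np.floating):
            if arr.min() < 0 or arr.max() > N_LEVELS - 1:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        else:
            raise ValueError(f"unsupported image dtype {arr.dtype}")
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Read a raster image (PNG/TIFF/PGM/PPM; JPEG read-only) as uint8.

    16-bit inputs are rescaled to 8 bits with ``round(v * 255 / 65535)``.
    Alpha channels are dropped.  Raises ``IOError`` on unreadable files and
    ``ValueError`` on unsupported sample formats.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) * 255.0 / 65535.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth/dtype {arr.dtype} in {path}")
    return validate_image(arr)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write an image buffer as PNG/PGM/PPM/TIFF (by extension)."""
    iio.imwrite(Path(path), validate_image(img))


def split_channels(img: np.ndarray) -> list[np.ndarray]:
    """Return the list of single-channel buffers of ``img``.

    Grayscale images come back as a one-element list containing the image
    itself; RGB images as three 2-D buffers in R, G, B order.  Color images
    are thresholded per channel (no joint 3-D histogram).
    """
    img = validate_image(img)
    if img.ndim == 2:
        return [img]
    return [np.ascontiguousarray(img[:, :, c]) for c in range(3)]


@dataclass(frozen=True)
class ChannelHistogram:
    """256-bin intensity histogram of one image channel.

    Attributes
    ----------
    counts : ndarray of int, shape (256,)
        Pixel tallies ``f_i`` per gray level.
    channel : str
        ``"gray"``, ``"R"``, ``"G"`` or ``"B"``.
    """

    counts: np.ndarray
    channel: str = "gray"
    _probs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValueError(f"counts must have length {N_LEVELS}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("histogram must contain at least one pixel")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "_probs", counts / counts.sum())

    @property
    def total(self) -> int:
        """Total pixel count N."""
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Normalized probabilities ``p_i = f_i / N`` (sum to 1)."""
        return self._probs

    def to_json(self) -> str:
        return json.dumps({"counts": self.counts.tolist(), "channel": self.channel})

    @classmethod
    def from_json(cls, text: str) -> "ChannelHistogram":
        obj = json.loads(text)
        return cls(np.asarray(obj["counts"]), obj.get("channel", "gray"))


def compute_histogram(channel: np.ndarray, channel_id: str = "gray") -> ChannelHistogram:
    """Tally the 256-bin histogram of a single-channel image."""
    channel = validate_image(channel)
    if channel.ndim != 2:
        raise ValueError("compute_histogram expects a single-channel image")
    counts = np.bincount(channel.ravel(), minlength=N_LEVELS)
    return ChannelHistogram(counts, channel_id)


def image_histograms(img: np.ndarray) -> list[ChannelHistogram]:
    """Per-channel histograms of a grayscale or RGB image."""
    channels = split_channels(img)
    if len(channels) == 1:
        return [compute_histogram(channels[0], "gray")]
    return [compute_histogram(ch, name) for ch, name in zip(channels, CHANNEL_NAMES)]
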