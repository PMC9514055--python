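"""Shared numerical helpers: seeded sub-streams and windowed Gaussian filters."""

from __future__ import annotations

import zlib

import numpy as np
from scipy import ndimage


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for a named sub-stream of ``master_seed``.

    All randomness in the package flows from one master seed through named
    sub-streams (e.g. ``substream(seed, "images", 7)``), so independent
    stages never share or reorder draws.  String keys are hashed with CRC32;
    integer keys are used as-is.
    """
    hashed = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            hashed.append(int(k) & 0x7FFFFFFF)
        else:
            hashed.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *hashed]))


def gaussian_kernel_1d(window: int, sd: float) -> np.ndarray:
    """Normalized 1-D Gaussian kernel of a fixed window size.

    Even window sizes are promoted to the next odd size so that the filter
    stays zero-phase (no half-pixel shift).
    """
    if window < 1 or sd <= 0:
        raise ValueError("window must be >= 1 and sd > 0")
    n = int(window)
    if n % 2 == 0:
        n += 1
    x = np.arange(n) - (n - 1) / 2.0
    k = np.exp(-0.5 * (x / float(sd)) ** 2)
    return k / k.sum()


def windowed_gaussian_filter(arr: np.ndarray, window: int, sd: float) -> np.ndarray:
    """Separable Gaussian blur with an explicit square kernel window.

    Borders are handled by reflection (symmetric padding), which conserves
    total mass for the normalized symmetric kernel.
    """
    k = gaussian_kernel_1d(window, sd)
    out = ndimage.convolve1d(np.asarray(arr, dtype=np.float64), k, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, k, axis=1, mode="reflect")
    return out
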