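"""Stain separation and two-channel correlation of histology images.

Trichrome-stained sections are unmixed by optical-density colour
deconvolution: each pixel's OD vector ``-log((I + eps)/white)`` is
projected through the pseudo-inverse of the stain matrix, giving per-stain
concentration images.  Extracellular-matrix abundance is then quantified
as the Pearson correlation between two channels, optionally summarised as
a joint (2D) histogram.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr

#: aniline blue / acid fuchsin unit OD vectors (RGB), the standard
#: Masson-trichrome pair used by ImageJ-style colour deconvolution
MTS_VECTORS = {
    "aniline-blue": (0.7995, 0.5913, 0.1053),
    "acid-fuchsin": (0.0916, 0.9545, 0.2835),
}

_OD_EPS = 1.0 / 255.0


class StainVectors:
    """2-3 named unit optical-density direction vectors in RGB space."""

    def __init__(self, vectors: dict):
        if not 2 <= len(vectors) <= 3:
            raise ValueError("need 2 or 3 stain vectors")
        names, rows = zip(*vectors.items())
        m = np.asarray(rows, dtype=float)
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be nonzero")
        m = m / norms[:, None]
        if np.linalg.matrix_rank(m, tol=1e-6) < len(names):
            raise ValueError("stain vectors must be pairwise non-collinear")
        self.names = list(names)
        self.matrix = m              # (n_stains, 3)
        self.pinv = np.linalg.pinv(m)  # (3, n_stains)

    @classmethod
    def mts(cls) -> "StainVectors":
        return cls(MTS_VECTORS)


def stain_separate(rgb: np.ndarray, vectors: StainVectors, white=None) -> dict:
    """Optical-density unmixing of an RGB image into stain concentrations.

    ``rgb`` may be in [0, 255] or [0, 1]; ``white`` is the per-channel
    white point (defaults to the image maximum per channel).  Returns a
    dict of per-stain concentration images, clipped at 0.
    """
    img = np.asarray(rgb, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("rgb must be (..., 3)")
    scale = 255.0 if img.max() > 1.5 else 1.0
    img = img / scale
    if white is None:
        white = img.reshape(-1, 3).max(axis=0)
    white = np.clip(np.asarray(white, dtype=float), _OD_EPS, None)
    od = -np.log((img + _OD_EPS) / (white + _OD_EPS))
    conc = od @ vectors.pinv            # (..., n_stains)
    conc = np.clip(conc, 0.0, None)
    return {name: conc[..., i] for i, name in enumerate(vectors.names)}


def render_stains(concentrations: dict, vectors: StainVectors, white=None) -> np.ndarray:
    """Forward model: compose concentration images back into RGB in [0, 1]."""
    names = vectors.names
    stack = np.stack([np.asarray(concentrations[n], float) for n in names], axis=-1)
    od = stack @ vectors.matrix
    white_arr = np.ones(3) if white is None else np.asarray(white, float)
    img = (white_arr + _OD_EPS) * np.exp(-od) - _OD_EPS
    return np.clip(img, 0.0, 1.0)


def channel_pearson(ch1, ch2, mask=None) -> float:
    """Pearson product-moment correlation between two channel images.

    Raises on fewer than 2 pixels after masking; returns nan (undefined)
    when either channel has zero variance.
    """
    a = np.asarray(ch1, dtype=float).ravel()
    b = np.asarray(ch2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("channels must have equal size")
    if mask is not None:
        m = np.asarray(mask, bool).ravel()
        a, b = a[m], b[m]
    if a.size < 2:
        raise ValueError("need >= 2 pixels after masking")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(pearsonr(a, b).statistic)


def joint_histogram(ch1, ch2, bins: int = 64, mask=None):
    """Joint 2D histogram of two channels.

    Returns ``(counts, edges1, edges2)``; counts sum to the number of
    (masked) pixels.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a = np.asarray(ch1, dtype=float).ravel()
    b = np.asarray(ch2, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask, bool).ravel()
        a, b = a[m], b[m]
    counts, e1, e2 = np.histogram2d(a, b, bins=bins)
    return counts, e1, e2
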