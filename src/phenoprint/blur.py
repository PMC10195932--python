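"""Temporal blurring of phenotype images.

Before clustering, each image A is blurred along the time axis:

    B(i, j) = max_{j-h <= k <= j+h} A(i, k) * exp(-(k - j)^2 / d)

with half-window h = 10 and decay d = 10 by default.  Each event thus
radiates a Gaussian-shaped halo up to 10 weeks in both directions, so
that Euclidean distance on blurred images treats two patients with the
same feature at nearby weeks as similar, instead of as maximally
different the way it would on the raw images.

The window is truncated at the matrix edges (no padding); since the
k = j term contributes A(i, j) itself, B >= A elementwise, and values
stay in [0, 1] whenever A does.
"""

from __future__ import annotations

import numpy as np

from .encoding import ImageStack, TemporalImage

__all__ = ["blur", "blur_stack", "blur_oracle", "kernel_weights"]


def kernel_weights(half_window: int = 10, decay: float = 10.0) -> np.ndarray:
    """Gaussian decay weights exp(-t^2/decay) for t = -h..h."""
    t = np.arange(-half_window, half_window + 1, dtype=float)
    return np.exp(-(t**2) / decay)


def _blur_array(A: np.ndarray, half_window: int, decay: float) -> np.ndarray:
    """Max-Gaussian blur along the last axis of a 2-D or 3-D array."""
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    if not decay > 0:
        raise ValueError("decay must be > 0")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix must be finite")
    W = A.shape[-1]
    B = np.array(A, dtype=float, copy=True)
    for t in range(1, half_window + 1):
        w = float(np.exp(-(t**2) / decay))
        # contribution of A(.., j+t) to B(.., j) and of A(.., j-t) to B(.., j)
        np.maximum(B[..., : W - t], w * A[..., t:], out=B[..., : W - t])
        np.maximum(B[..., t:], w * A[..., : W - t], out=B[..., t:])
    return B


def blur(image, half_window: int = 10, decay: float = 10.0):
    """Blur a single image (TemporalImage or 2-D array) along time.

    Returns the same type as the input.
    """
    if isinstance(image, TemporalImage):
        return TemporalImage(image.patient_id, _blur_array(image.matrix, half_window, decay))
    return _blur_array(np.asarray(image, dtype=float), half_window, decay)


def blur_stack(stack: ImageStack, half_window: int = 10, decay: float = 10.0) -> ImageStack:
    """Blur every image of a cohort stack."""
    return ImageStack(list(stack.patient_ids), _blur_array(stack.array, half_window, decay))


def blur_oracle(image, half_window: int = 10, decay: float = 10.0):
    """Reference implementation by explicit loops over (i, j, k).

    Kept deliberately naive; used in tests to cross-check :func:`blur`.
    """
    A = image.matrix if isinstance(image, TemporalImage) else np.asarray(image, dtype=float)
    F, W = A.shape
    B = np.zeros_like(A, dtype=float)
    for i in range(F):
        for j in range(W):
            best = 0.0
            for k in range(max(0, j - half_window), min(W - 1, j + half_window) + 1):
                v = A[i, k] * np.exp(-((k - j) ** 2) / decay)
                if v > best:
                    best = v
            B[i, j] = best
    if isinstance(image, TemporalImage):
        return TemporalImage(image.patient_id, B)
    return B
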