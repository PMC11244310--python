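"""Grey-relational primitives shared by the noise filter and the segmenter.

Grey relational analysis scores the similarity of a comparison value to a
reference value with a coefficient in (0, 1]; here the coefficient is
``1 / (1 + |a - b|)``, evaluated on the 0-255 intensity scale, so that equal
intensities score 1 and the maximal 8-bit difference scores 1/256.  The
noise detector ranks a 3x3 window's nine coefficients ascending ("association
order"); a center pixel whose coefficient lands among the three smallest is
declared an impulse-noise candidate.

Intensities are processed on the 0-255 scale throughout: the +1 in the
coefficient denominator only discriminates usefully at that scale.
"""

from __future__ import annotations

import numpy as np

#: row-major position of the center pixel in a flattened 3x3 window (0-based)
CENTER = 4


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("intensities must be finite")


def grey_coefficient(a, b):
    """Grey relational coefficient ``1 / (1 + |a - b|)``.

    Symmetric, strictly decreasing in ``|a - b|``, equal to 1 iff ``a == b``.
    Accepts scalars or broadcastable arrays; always returns floats in (0, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_finite(a, b)
    out = 1.0 / (1.0 + np.abs(a - b))
    return float(out) if out.ndim == 0 else out


def window_coefficients(window, reference):
    """Coefficients of the nine window values against a scalar reference.

    ``window`` is a row-major flattened 3x3 neighborhood (length 9);
    ``reference`` is typically the window median (noise detection) or the
    window mean (edge degree).
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (9,):
        raise ValueError(f"window must have exactly 9 values, got shape {w.shape}")
    return grey_coefficient(reference, w)


def association_rank_of_center(coeffs) -> int:
    """1-based rank of the center coefficient in the ascending association order.

    Ties are broken by original window position (stable sort), so on a
    constant window the center — position 5 of 9 — ranks 5th and is judged
    normal rather than noisy.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (9,):
        raise ValueError(f"expected 9 coefficients, got shape {c.shape}")
    center = c[CENTER]
    below = int(np.count_nonzero(c < center))
    tied_before = int(np.count_nonzero(c[:CENTER] == center))
    return below + tied_before + 1


def windows3(image: np.ndarray) -> np.ndarray:
    """All 3x3 neighborhoods of ``image`` as an (M, N, 9) row-major stack.

    Borders are replicate-padded by one pixel so every pixel, border
    included, owns a full window and the output matches the input size.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    _check_finite(img)
    padded = np.pad(img, 1, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, (3, 3))
    return view.reshape(img.shape[0], img.shape[1], 9)


def coefficient_field(image: np.ndarray, reference: str = "median"):
    """Per-pixel window coefficients for a whole image, vectorized.

    Returns ``(coeffs, ref)`` where ``coeffs`` is (M, N, 9) and ``ref`` the
    (M, N) reference map — the exact 5th order statistic of each window for
    ``"median"``, the window mean for ``"mean"``.
    """
    w = windows3(image)
    if reference == "median":
        ref = np.median(w, axis=-1)
    elif reference == "mean":
        ref = w.mean(axis=-1)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    coeffs = 1.0 / (1.0 + np.abs(ref[..., None] - w))
    return coeffs, ref
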