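"""Intensity preprocessing: non-parametric bias correction and equalization.

Low-frequency multiplicative intensity inhomogeneity (coil shading) is
estimated in the log domain by iteratively fitting a heavily smoothed
residual field, then divided out; global histogram equalization follows to
normalize contrast.  Both steps operate per b-value volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_volumes import Volume, quantize

__all__ = ["BiasField", "correct_bias", "equalize_histogram", "preprocess_volume"]


@dataclass
class BiasField:
    """Smooth multiplicative field; strictly positive, mean ~ 1."""

    field: np.ndarray

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.float64)
        if not np.all(self.field > 0):
            raise ValueError("bias field must be strictly positive")


def correct_bias(v: Volume, smoothness_mm: float = 25.0, max_iter: int = 8,
                 ) -> tuple[Volume, BiasField]:
    """Estimate and remove a smooth multiplicative bias field.

    The observed image is modelled as ``g = u * f`` with ``u`` the true image
    and ``f`` a low-frequency positive field.  In the log domain the field is
    additive; each iteration low-pass filters the current log-residual with a
    Gaussian of physical scale ``smoothness_mm`` and accumulates it into the
    field estimate.  The estimate is normalized to unit geometric mean so the
    global intensity scale is untouched.

    Returns the corrected (re-quantized) volume and the estimated field.
    An all-zero volume is a no-op with a unit field.
    """
    data = v.data.astype(np.float64)
    fg = data > 0
    if not fg.any():
        return Volume(v.data.copy(), v.spacing, v.q_levels), BiasField(np.ones(v.dims))

    sigma_vox = tuple(smoothness_mm / s for s in v.spacing)
    log_g = np.log(np.where(fg, data, 1.0))
    log_field = np.zeros_like(log_g)
    # smoothing over the foreground only: normalize by the smoothed mask so
    # the background zeros do not drag the field down near the object rim
    w = ndimage.gaussian_filter(fg.astype(np.float64), sigma_vox)
    w = np.maximum(w, 1e-6)
    for _ in range(max_iter):
        resid = np.where(fg, log_g - log_field, 0.0)
        local_mean = ndimage.gaussian_filter(resid, sigma_vox) / w
        # the low-frequency part of the residual, re-centred on the foreground
        local_mean -= local_mean[fg].mean()
        log_field += local_mean
    log_field -= log_field[fg].mean()  # unit geometric mean over foreground
    field = np.exp(log_field)
    corrected = np.where(fg, data / field, data)
    corrected = np.clip(np.rint(corrected), 0, v.q_levels - 1).astype(np.int32)
    return Volume(corrected, v.spacing, v.q_levels), BiasField(field)


def equalize_histogram(v: Volume) -> Volume:
    """Global histogram equalization over the gray-level set {0..Q-1}.

    The mapping is the (monotone non-decreasing) empirical CDF rescaled to
    the gray-level range, so level sets of the input are preserved and the
    output CDF deviates from uniform by at most the largest bin mass.
    """
    q = v.q_levels
    hist = np.bincount(v.data.ravel(), minlength=q).astype(np.float64)
    cdf = np.cumsum(hist) / hist.sum()
    # anchor the lowest occupied level at its own CDF step so that an already
    # uniform histogram maps (near-)identically
    cdf_min = cdf[np.nonzero(hist)[0][0]] if hist.any() else 0.0
    denom = max(1.0 - cdf_min, 1e-12)
    mapping = np.rint((cdf - cdf_min) / denom * (q - 1)).astype(np.int32)
    mapping = np.clip(mapping, 0, q - 1)
    return Volume(mapping[v.data], v.spacing, v.q_levels)


def preprocess_volume(v: Volume, smoothness_mm: float = 25.0, max_iter: int = 8,
                      bias: bool = True, equalize: bool = True) -> Volume:
    """Bias correction followed by histogram equalization (pipeline order)."""
    out = v
    if bias:
        out, _ = correct_bias(out, smoothness_mm=smoothness_mm, max_iter=max_iter)
    if equalize:
        out = equalize_histogram(out)
    return out
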