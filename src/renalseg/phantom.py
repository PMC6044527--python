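"""Synthetic multi-subject, multi-b-value kidney phantoms with ground truth.

Each subject is a bean-shaped kidney (a deformed ellipsoid with a hilum
notch) carrying a cortex shell around a medulla interior, embedded in mixed
background tissue.  Per b-value signal follows the mono-exponential decay
``S_b = S0 * exp(-b * ADC)`` for each tissue, degraded by Rician noise (the
magnitude-MR noise model) and a smooth multiplicative bias field.  Random
smooth deformations of the kidney shape emulate inter-subject anatomical
variability, so a cohort supports leave-one-subject-out experiments against
the per-subject ground-truth masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .io_volumes import DWISeries, RegionMap, Volume, quantize

__all__ = ["PhantomSpec", "generate_subject", "generate_cohort", "leave_one_out"]


@dataclass
class PhantomSpec:
    """Generator configuration; ``seed`` fixes all randomness.

    ADC values are in mm^2/s and b-values in s/mm^2, so ``b * ADC`` is
    dimensionless.  ``noise_sigma`` is the Rician channel noise in gray
    levels of the noise-free S0 scale; ``bias_amplitude`` is the peak
    relative deviation of the multiplicative bias field from unity.
    """

    dims: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.28, 1.28, 4.0)
    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0)
    adc_cortex: float = 2.0e-3
    adc_medulla: float = 1.8e-3
    adc_background: tuple[float, float] = (1.0e-3, 2.5e-3)
    s0_cortex: float = 185.0
    s0_medulla: float = 160.0
    s0_background: float = 105.0
    noise_sigma: float = 4.0
    bias_amplitude: float = 0.2
    deform_amplitude: float = 3.0
    n_subjects: int = 8
    q_levels: int = 256
    seed: int = 0


def _smooth_noise(rng: np.random.Generator, dims: Sequence[int],
                  sigma_vox: float) -> np.ndarray:
    """Zero-mean unit-max smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(dims), sigma_vox)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _kidney_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Bean shape: ellipsoid minus a hilum notch, smoothly deformed per subject."""
    nx, ny, nz = spec.dims
    if min(spec.dims) < 16:
        raise ValueError(f"dims {spec.dims} too small for the kidney shape")
    x, y, z = np.meshgrid(
        np.arange(nx, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nz, dtype=np.float64),
        indexing="ij",
    )
    # random smooth deformation of the coordinate grid (inter-subject variability)
    amp = spec.deform_amplitude
    dx = amp * _smooth_noise(rng, spec.dims, sigma_vox=6.0)
    dy = amp * _smooth_noise(rng, spec.dims, sigma_vox=6.0)
    dz = amp * _smooth_noise(rng, spec.dims, sigma_vox=6.0)
    xd, yd, zd = x + dx, y + dy, z + dz

    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.30 * nx, 0.22 * ny, 0.26 * nz
    ellipsoid = (((xd - cx) / ax) ** 2 + ((yd - cy) / ay) ** 2
                 + ((zd - cz) / az) ** 2) <= 1.0
    # hilum: a notch carved from one side
    notch = (((xd - (cx + 0.9 * ax)) / (0.45 * ax)) ** 2
             + ((yd - cy) / (0.35 * ay)) ** 2
             + ((zd - cz) / (0.45 * az)) ** 2) <= 1.0
    mask = ellipsoid & ~notch
    # keep a single connected component (largest)
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("degenerate phantom: empty kidney mask")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def generate_subject(spec: PhantomSpec, subject_index: int,
                     ) -> tuple[DWISeries, RegionMap]:
    """One phantom subject: a DWI series plus its ground-truth kidney map."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index]))
    kidney = _kidney_mask(spec, rng)
    medulla = ndimage.binary_erosion(kidney, iterations=3)
    cortex = kidney & ~medulla

    # background tissue mixture: smoothly varying ADC and mottled S0
    lo, hi = spec.adc_background
    mix = 0.5 * (1.0 + _smooth_noise(rng, spec.dims, sigma_vox=4.0))
    adc_bg = lo + (hi - lo) * mix
    s0_bg = spec.s0_background * (1.0 + 0.15 * _smooth_noise(rng, spec.dims, 3.0))

    adc = np.where(cortex, spec.adc_cortex,
                   np.where(medulla, spec.adc_medulla, adc_bg))
    s0 = np.where(cortex, spec.s0_cortex,
                  np.where(medulla, spec.s0_medulla, s0_bg))

    bias = 1.0 + spec.bias_amplitude * _smooth_noise(rng, spec.dims, sigma_vox=12.0)

    volumes = []
    for b in spec.b_values:
        signal = s0 * np.exp(-b * adc)
        if spec.noise_sigma > 0:
            n1 = rng.normal(0.0, spec.noise_sigma, spec.dims)
            n2 = rng.normal(0.0, spec.noise_sigma, spec.dims)
            signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)  # Rician magnitude
        signal = signal * bias
        data = np.clip(np.rint(signal), 0, spec.q_levels - 1).astype(np.int32)
        volumes.append(Volume(data, spacing=spec.spacing, q_levels=spec.q_levels))

    series = DWISeries(b_values=spec.b_values, volumes=volumes,
                       subject_id=f"phantom{subject_index:02d}")
    truth = RegionMap(kidney.astype(np.uint8), spacing=spec.spacing)
    return series, truth


def generate_cohort(spec: PhantomSpec,
                    ) -> list[tuple[DWISeries, RegionMap]]:
    """A reproducible cohort of ``spec.n_subjects`` phantom subjects."""
    if spec.n_subjects < 3:
        raise ValueError("a cohort needs at least 3 subjects")
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


def leave_one_out(cohort: Sequence[tuple[DWISeries, RegionMap]],
                  ) -> Iterator[tuple[int, tuple[DWISeries, RegionMap],
                                      list[tuple[DWISeries, RegionMap]]]]:
    """Yield ``(test_index, test_subject, training_subjects)`` folds.

    The test subject is excluded from the training set used to build the
    shape-prior database.
    """
    for i in range(len(cohort)):
        train = [s for j, s in enumerate(cohort) if j != i]
        yield i, cohort[i], train
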