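"""Appearance-adaptive probabilistic shape prior.

A shape database is built by nonrigidly co-aligning the training b0 scans
(and their expert kidney maps) to a reference subject chosen by normalized
cross-correlation with the test scan.  The prior for a test image is then
*adapted* to its appearance: each test voxel is mapped through the
co-aligning deformation field into the database lattice, and a growing 3D
window around the mapped location is searched, across all aligned training
volumes, for voxels whose intensity matches the test voxel within a
tolerance; the kidney probability is the relative occurrence of the kidney
label among the matches.  The adaptive window makes the prior robust to
residual registration misalignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_volumes import RegionMap, Volume

__all__ = [
    "DeformationField",
    "ShapeDatabase",
    "ShapePrior",
    "select_reference",
    "register_nonrigid",
    "build_shape_database",
    "adapt_shape_prior",
]


@dataclass
class DeformationField:
    """Per-voxel displacements (voxel units) from fixed-lattice coordinates
    into moving-lattice coordinates: ``warped(x) = moving(x + disp[:, x])``."""

    disp: np.ndarray  # shape (3, X, Y, Z)

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError("deformation field must have shape (3, X, Y, Z)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("deformation field must be finite")

    @classmethod
    def identity(cls, dims: tuple[int, int, int]) -> "DeformationField":
        return cls(np.zeros((3, *dims)))

    def map_coordinates(self) -> np.ndarray:
        """Absolute sampling coordinates x + d(x), shape (3, X, Y, Z)."""
        grids = np.meshgrid(*[np.arange(n) for n in self.disp.shape[1:]],
                            indexing="ij")
        return np.stack(grids) + self.disp


def _normalize(data: np.ndarray) -> np.ndarray:
    data = data.astype(np.float64)
    lo, hi = data.min(), data.max()
    return (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)


def _centroid(data: np.ndarray) -> np.ndarray:
    total = data.sum()
    if total <= 0:
        return (np.asarray(data.shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(n) for n in data.shape], indexing="ij")
    return np.array([(g * data).sum() / total for g in grids])


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """NCC of two equally shaped arrays; invariant to affine rescaling."""
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def select_reference(candidates: Sequence[Volume], test: Volume) -> int:
    """Index of the candidate maximizing NCC with the test volume.

    Candidates are rigidly pre-aligned to the test by an integer shift of
    their intensity centroids.  Ties break to the lowest index.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    t = test.data.astype(np.float64)
    ct = _centroid(t)
    best_idx, best_ncc = 0, -np.inf
    for i, cand in enumerate(candidates):
        c = cand.data.astype(np.float64)
        shift = np.rint(ct - _centroid(c)).astype(int)
        aligned = ndimage.shift(c, shift, order=0, mode="constant", cval=0.0)
        ncc = normalized_cross_correlation(aligned, t)
        if ncc > best_ncc + 1e-12:
            best_idx, best_ncc = i, ncc
    return best_idx


def _warp(data: np.ndarray, field: DeformationField, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(
        data.astype(np.float64), field.map_coordinates(), order=order,
        mode="nearest",
    )


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float((d * d).sum())


def register_nonrigid(moving: Volume, fixed: Volume, levels: int = 3,
                      iters_per_level: int = 30, sigma_fluid: float = 1.0,
                      sigma_elastic: float = 1.5, step_cap: float = 1.5,
                      ) -> tuple[DeformationField, Volume]:
    """Multi-resolution SSD-minimizing deformable registration.

    A demons-style scheme: at each resolution the displacement field is
    refined by the normalized SSD gradient, with Gaussian fluid smoothing of
    each update and elastic smoothing of the accumulated field.  The
    returned field is the best-SSD iterate seen at full resolution, so
    ``SSD(warped, fixed) <= SSD(moving, fixed)`` by construction and SSD is
    non-increasing across levels.
    """
    if moving.dims != fixed.dims:
        raise ValueError("resample volumes to equal dims before registration")
    mov = _normalize(moving.data)
    fix = _normalize(fixed.data)
    dims = np.asarray(fixed.dims)

    best_field = DeformationField.identity(fixed.dims)
    best_ssd = _ssd(mov, fix)
    field = np.zeros((3, *fixed.dims))

    for level in range(levels - 1, -1, -1):
        factor = 2**level
        shape_l = tuple(max(4, int(np.ceil(n / factor))) for n in dims)
        zoom_down = [s / n for s, n in zip(shape_l, dims)]
        mov_l = ndimage.zoom(ndimage.gaussian_filter(mov, max(factor / 2, 0.01)),
                             zoom_down, order=1)
        fix_l = ndimage.zoom(ndimage.gaussian_filter(fix, max(factor / 2, 0.01)),
                             zoom_down, order=1)
        field_l = np.stack([
            ndimage.zoom(field[ax], [s / n for s, n in zip(shape_l, dims)],
                         order=1) * (shape_l[ax] / dims[ax])
            for ax in range(3)
        ])
        for _ in range(iters_per_level):
            warped = _warp(mov_l, DeformationField(field_l))
            diff = warped - fix_l
            grads = np.gradient(warped)
            gmag2 = sum(g * g for g in grads)
            denom = gmag2 + diff * diff + 1e-9
            update = np.stack([-diff * g / denom for g in grads])
            norm = np.sqrt((update**2).sum(axis=0))
            scale = np.minimum(1.0, step_cap / np.maximum(norm, 1e-12))
            update *= scale
            update = np.stack(
                [ndimage.gaussian_filter(u, sigma_fluid) for u in update]
            )
            field_l = field_l + update
            field_l = np.stack(
                [ndimage.gaussian_filter(f, sigma_elastic) for f in field_l]
            )
        # back to full resolution; keep only if SSD improves
        field_full = np.stack([
            ndimage.zoom(field_l[ax], [n / s for s, n in zip(shape_l, dims)],
                         order=1) * (dims[ax] / shape_l[ax])
            for ax in range(3)
        ])
        ssd = _ssd(_warp(mov, DeformationField(field_full)), fix)
        if ssd < best_ssd:
            best_field = DeformationField(field_full)
            best_ssd = ssd
            field = field_full
        else:
            field = best_field.disp

    warped_best = _warp(moving.data.astype(np.float64), best_field)
    warped_v = Volume(
        np.clip(np.rint(warped_best), 0, moving.q_levels - 1).astype(np.int32),
        spacing=fixed.spacing, q_levels=moving.q_levels,
    )
    return best_field, warped_v


@dataclass
class ShapeDatabase:
    """Co-aligned training volumes and maps on the reference lattice."""

    reference_id: int
    volumes: np.ndarray  # (S, X, Y, Z) int32 aligned b0 intensities
    maps: np.ndarray  # (S, X, Y, Z) uint8 aligned binary maps
    fields: list[DeformationField]
    spacing: tuple[float, float, float]
    q_levels: int = 256

    def __post_init__(self) -> None:
        uniq = np.unique(self.maps)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("aligned maps must stay binary")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.volumes.shape[1:])


@dataclass
class ShapePrior:
    """Voxel-wise kidney probability ``Pr_sp:p(1)`` on the test lattice."""

    pr1: np.ndarray

    def __post_init__(self) -> None:
        self.pr1 = np.asarray(self.pr1, dtype=np.float64)
        if self.pr1.min() < 0 or self.pr1.max() > 1:
            raise ValueError("prior probabilities must lie in [0, 1]")

    def pr(self, l: int) -> np.ndarray:
        return self.pr1 if l == 1 else 1.0 - self.pr1

    @classmethod
    def uniform(cls, dims: tuple[int, int, int]) -> "ShapePrior":
        return cls(np.full(dims, 0.5))


def build_shape_database(training: Sequence[tuple[Volume, RegionMap]],
                         reference_id: int, levels: int = 3,
                         iters_per_level: int = 30) -> ShapeDatabase:
    """Co-align every training subject to the reference subject.

    Volumes are registered by SSD; maps are warped through the same fields
    with nearest-neighbor interpolation so they stay binary.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training subjects")
    ref_vol, _ = training[reference_id]
    dims = ref_vol.dims
    vols, maps, fields = [], [], []
    for i, (vol, rmap) in enumerate(training):
        if vol.dims != dims or rmap.dims != dims:
            raise ValueError(
                f"training subject {i} dims {vol.dims} != reference {dims}"
            )
        if i == reference_id:
            f = DeformationField.identity(dims)
            vols.append(vol.data.astype(np.int32))
            maps.append(rmap.labels.astype(np.uint8))
        else:
            f, warped = register_nonrigid(vol, ref_vol, levels=levels,
                                          iters_per_level=iters_per_level)
            vols.append(warped.data.astype(np.int32))
            warped_map = ndimage.map_coordinates(
                rmap.labels, f.map_coordinates(), order=0, mode="constant",
                cval=0,
            ).astype(np.uint8)
            maps.append(warped_map)
        fields.append(f)
    return ShapeDatabase(
        reference_id=reference_id,
        volumes=np.stack(vols),
        maps=np.stack(maps),
        fields=fields,
        spacing=ref_vol.spacing,
        q_levels=ref_vol.q_levels,
    )


def align_test(test: Volume, db: ShapeDatabase, levels: int = 3,
               iters_per_level: int = 30) -> DeformationField:
    """Field on the test lattice mapping test voxels into database coords.

    Obtained by registering the database reference volume onto the test
    volume, so that ``p_db = p_test + disp[:, p_test]``.
    """
    ref = Volume(db.volumes[db.reference_id], spacing=db.spacing,
                 q_levels=db.q_levels)
    field, _ = register_nonrigid(ref, test, levels=levels,
                                 iters_per_level=iters_per_level)
    return field


def adapt_shape_prior(test: Volume, db: ShapeDatabase,
                      window0: tuple[int, int, int] = (3, 3, 3),
                      intensity_tol: int = 10,
                      max_window: tuple[int, int, int] = (11, 11, 11),
                      field: DeformationField | None = None,
                      ) -> ShapePrior:
    """Adapt the shape prior to the test image's appearance.

    For each test voxel, the co-aligning field maps it into the database
    lattice; a window (initially ``window0``, grown by +2 per axis up to
    ``max_window``) centered there is searched across all aligned training
    volumes for intensities within ``intensity_tol`` gray levels of the test
    voxel's.  ``Pr_sp:p(1)`` is the fraction of kidney labels among the
    matches.  If the largest window still has no intensity match, the label
    relative occurrence in that window (ignoring intensity) is used.
    The procedure is deterministic.
    """
    if any(w % 2 == 0 for w in window0):
        raise ValueError("window0 must be odd-sized in every axis")
    if field is None:
        field = align_test(test, db)
    dims = test.dims
    db_dims = db.dims
    n_sub = db.volumes.shape[0]

    mapped = np.rint(field.map_coordinates()).astype(np.int64)
    for ax in range(3):
        np.clip(mapped[ax], 0, db_dims[ax] - 1, out=mapped[ax])
    mapped_flat = mapped.reshape(3, -1)
    g_test = test.data.reshape(-1).astype(np.int64)

    n_vox = g_test.size
    pr1 = np.full(n_vox, 0.5)
    active = np.arange(n_vox)

    window = list(window0)
    flat_vols = db.volumes.reshape(n_sub, -1).astype(np.int64)
    flat_maps = db.maps.reshape(n_sub, -1).astype(np.int64)
    strides = (db_dims[1] * db_dims[2], db_dims[2], 1)

    while active.size:
        radii = [w // 2 for w in window]
        kidney = np.zeros(active.size, dtype=np.int64)
        total = np.zeros(active.size, dtype=np.int64)
        any_k = np.zeros(active.size, dtype=np.int64)  # intensity-free fallback
        any_t = np.zeros(active.size, dtype=np.int64)
        base = mapped_flat[:, active]
        gt = g_test[active]
        for off in itertools.product(*[range(-r, r + 1) for r in radii]):
            coords = base + np.asarray(off)[:, None]
            inside = np.ones(active.size, dtype=bool)
            for ax in range(3):
                inside &= (coords[ax] >= 0) & (coords[ax] < db_dims[ax])
            cc = np.where(inside, coords, 0)
            flat_idx = cc[0] * strides[0] + cc[1] * strides[1] + cc[2]
            for s in range(n_sub):
                ints = flat_vols[s, flat_idx]
                labs = flat_maps[s, flat_idx]
                match = inside & (np.abs(ints - gt) <= intensity_tol)
                kidney += np.where(match, labs, 0)
                total += match
                any_k += np.where(inside, labs, 0)
                any_t += inside
        found = total > 0
        pr1[active[found]] = kidney[found] / total[found]
        at_max = all(w >= mw for w, mw in zip(window, max_window))
        if at_max:
            rest = ~found
            # no intensity match anywhere: fall back to label occurrences
            safe = np.maximum(any_t[rest], 1)
            pr1[active[rest]] = any_k[rest] / safe
            break
        active = active[~found]
        window = [min(w + 2, mw) for w, mw in zip(window, max_window)]

    return ShapePrior(pr1.reshape(dims))
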