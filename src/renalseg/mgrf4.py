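"""4th-order Markov-Gibbs random field over binary region maps.

Spatial label dependencies on the nearest 26-neighborhood are modelled by
translation-invariant clique families of order 2 (pairs), 3 (collinear
triples) and 4 (planar 2x2 quadruples).  Gibbs potentials are estimated
*analytically* from the relative frequencies of label-equality classes in a
map: with equiprobable binary labels, per-configuration probabilities are
1/4 (pairs), 1/8 (triples) and 1/16 (quadruples), and deviations of the
observed equality-class frequencies from their baselines give

    V2:eq  = 4 (F_eq  - 1/2) = -V2:ne
    V3:eq3 = (16/3)(F_eq3 - 1/4) = -V3:eq2
    V4     = lambda* (f4, f3, f2),   f4 = F_eq4 - 1/8,
                                     f3 = F_eq3 - 1/2,
                                     f2 = F_eq2 - 3/8

with the shared scale lambda* = sum(f4^2+f3^2+f2^2) /
sum(7/64 f4^2 + 1/4 f3^2 + 15/64 f2^2) over the quadruple families.
Quadruple equality classes (binary labels, k = number of ones): ``eq4`` is
k in {0,4} (baseline 1/8), ``eq3`` is k in {1,3} (exactly three equal,
baseline 1/2), ``eq2`` is k = 2 (two-and-two, baseline 3/8).

Only *conditional* voxel-wise probabilities ``Pr_V:p(l)`` are ever needed
downstream, so the partition function is never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .io_volumes import RegionMap

__all__ = [
    "CliqueFamily",
    "ConfigFrequencies",
    "GibbsPotentials",
    "default_families",
    "config_frequencies",
    "estimate_potentials",
    "gibbs_energy",
    "spatial_probability_volume",
    "spatial_label_probability",
    "gibbs_sample",
]


@dataclass(frozen=True)
class CliqueFamily:
    """All translates of one fixed voxel-offset pattern.

    ``offsets`` includes the anchor ``(0,0,0)``; every offset lies in the
    26-neighborhood (all components in {-1, 0, 1} relative to the anchor,
    except collinear-triple ends which sit one step either side of it).
    """

    family_id: str
    order: int
    offsets: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.order != len(self.offsets):
            raise ValueError("clique order must equal the number of offsets")
        if self.order not in (2, 3, 4):
            raise ValueError("clique order must be 2, 3 or 4")
        for off in self.offsets:
            if max(abs(c) for c in off) > 1:
                raise ValueError(f"offset {off} outside the 26-neighborhood")


def _directions_26() -> list[tuple[int, int, int]]:
    """The 13 distinct directions of the 26-neighborhood (modulo sign)."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if d > tuple(-c for c in d):  # canonical sign representative
                    dirs.append(d)
    return sorted(dirs)


def default_families() -> list[CliqueFamily]:
    """13 pair, 13 collinear-triple and 9 planar 2x2 quadruple families."""
    fams: list[CliqueFamily] = []
    dirs = _directions_26()
    for i, d in enumerate(dirs):
        fams.append(CliqueFamily(f"p{i:02d}", 2, ((0, 0, 0), d)))
    for i, d in enumerate(dirs):
        neg = tuple(-c for c in d)
        fams.append(CliqueFamily(f"t{i:02d}", 3, (neg, (0, 0, 0), d)))
    axes = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    quads: list[tuple[tuple[int, int, int], tuple[int, int, int]]] = [
        (axes[0], axes[1]),
        (axes[0], axes[2]),
        (axes[1], axes[2]),
        (axes[0], (0, 1, 1)),
        (axes[0], (0, 1, -1)),
        (axes[1], (1, 0, 1)),
        (axes[1], (1, 0, -1)),
        (axes[2], (1, 1, 0)),
        (axes[2], (1, -1, 0)),
    ]
    for i, (u, v) in enumerate(quads):
        uv = tuple(a + b for a, b in zip(u, v))
        fams.append(CliqueFamily(f"q{i:02d}", 4, ((0, 0, 0), u, v, uv)))
    return fams


def _collinear_offsets(fam: CliqueFamily) -> bool:
    (a, b, c) = fam.offsets
    va = tuple(y - x for x, y in zip(a, b))
    vb = tuple(y - x for x, y in zip(b, c))
    return va == vb


def _shifted_views(arr: np.ndarray, offsets: Sequence[tuple[int, int, int]],
                   ) -> list[np.ndarray] | None:
    """Equally-shaped views v_i with v_i[p] = arr[p + offsets[i]].

    Anchors are restricted to positions where the whole clique fits the
    lattice (cliques crossing the boundary are skipped).  Returns None when
    no anchor position is valid.
    """
    lo = [max(0, -min(off[ax] for off in offsets)) for ax in range(3)]
    hi = [arr.shape[ax] - max(0, max(off[ax] for off in offsets)) for ax in range(3)]
    if any(h <= l for l, h in zip(lo, hi)):
        return None
    views = []
    for off in offsets:
        sl = tuple(
            slice(lo[ax] + off[ax], hi[ax] + off[ax]) for ax in range(3)
        )
        views.append(arr[sl])
    return views


@dataclass
class ConfigFrequencies:
    """Per-family relative frequencies of the label-equality classes."""

    pair_eq: dict[str, float] = field(default_factory=dict)
    triple_eq3: dict[str, float] = field(default_factory=dict)
    quad: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    # quad values are (F_eq4, F_eq3, F_eq2); each family's classes sum to 1


def config_frequencies(m: RegionMap | np.ndarray,
                       families: Sequence[CliqueFamily] | None = None,
                       ) -> ConfigFrequencies:
    """Empirical equality-class frequencies over all cliques of each family."""
    labels = m.labels if isinstance(m, RegionMap) else np.asarray(m)
    if not np.all(np.isin(np.unique(labels), (0, 1))):
        raise ValueError("region map must be binary")
    if min(labels.shape) < 3:
        raise ValueError("map dims must be >= 3 in every axis")
    labels = labels.astype(np.int8)
    families = default_families() if families is None else families
    out = ConfigFrequencies()
    for fam in families:
        views = _shifted_views(labels, fam.offsets)
        if views is None:
            raise ValueError(f"no clique of family {fam.family_id} fits the lattice")
        s = sum(v.astype(np.int32) for v in views)
        n = s.size
        if fam.order == 2:
            out.pair_eq[fam.family_id] = float(np.count_nonzero((s == 0) | (s == 2)) / n)
        elif fam.order == 3:
            out.triple_eq3[fam.family_id] = float(
                np.count_nonzero((s == 0) | (s == 3)) / n
            )
        else:
            eq4 = np.count_nonzero((s == 0) | (s == 4)) / n
            eq3 = np.count_nonzero((s == 1) | (s == 3)) / n
            eq2 = np.count_nonzero(s == 2) / n
            out.quad[fam.family_id] = (float(eq4), float(eq3), float(eq2))
    return out


@dataclass
class GibbsPotentials:
    """Analytic potential estimates; antisymmetric identities by construction."""

    pair_eq: dict[str, float]
    triple_eq3: dict[str, float]
    quad: dict[str, tuple[float, float, float]]  # (V_eq4, V_eq3, V_eq2)
    lambda_star: float

    def pair_ne(self, fid: str) -> float:
        return -self.pair_eq[fid]

    def triple_eq2(self, fid: str) -> float:
        return -self.triple_eq3[fid]

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "pair_eq": self.pair_eq,
                "triple_eq3": self.triple_eq3,
                "quad": {k: list(v) for k, v in self.quad.items()},
                "lambda_star": self.lambda_star,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GibbsPotentials":
        import json

        obj = json.loads(text)
        return cls(
            pair_eq=obj["pair_eq"],
            triple_eq3=obj["triple_eq3"],
            quad={k: tuple(v) for k, v in obj["quad"].items()},
            lambda_star=obj["lambda_star"],
        )

    @classmethod
    def zeros(cls, families: Sequence[CliqueFamily]) -> "GibbsPotentials":
        return cls(
            pair_eq={f.family_id: 0.0 for f in families if f.order == 2},
            triple_eq3={f.family_id: 0.0 for f in families if f.order == 3},
            quad={f.family_id: (0.0, 0.0, 0.0) for f in families if f.order == 4},
            lambda_star=0.0,
        )


def estimate_potentials(freqs: ConfigFrequencies) -> GibbsPotentials:
    """Plug-in analytic potential estimates from equality-class frequencies."""
    pair_eq = {fid: 4.0 * (F - 0.5) for fid, F in freqs.pair_eq.items()}
    triple_eq3 = {fid: (16.0 / 3.0) * (F - 0.25)
                  for fid, F in freqs.triple_eq3.items()}
    f_terms = {
        fid: (F4 - 1.0 / 8.0, F3 - 1.0 / 2.0, F2 - 3.0 / 8.0)
        for fid, (F4, F3, F2) in freqs.quad.items()
    }
    num = sum(f4**2 + f3**2 + f2**2 for f4, f3, f2 in f_terms.values())
    den = sum(
        (7.0 / 64.0) * f4**2 + (1.0 / 4.0) * f3**2 + (15.0 / 64.0) * f2**2
        for f4, f3, f2 in f_terms.values()
    )
    lam = num / den if den > 0 else 0.0
    quad = {fid: (lam * f4, lam * f3, lam * f2)
            for fid, (f4, f3, f2) in f_terms.items()}
    return GibbsPotentials(pair_eq=pair_eq, triple_eq3=triple_eq3, quad=quad,
                           lambda_star=lam)


def second_order_only(V: GibbsPotentials) -> GibbsPotentials:
    """Ablation: zero out the 3rd/4th-order potentials (pairwise model)."""
    return GibbsPotentials(
        pair_eq=dict(V.pair_eq),
        triple_eq3={k: 0.0 for k in V.triple_eq3},
        quad={k: (0.0, 0.0, 0.0) for k in V.quad},
        lambda_star=0.0,
    )


def _clique_potential_sums(labels: np.ndarray, fam: CliqueFamily,
                           V: GibbsPotentials) -> float:
    views = _shifted_views(labels, fam.offsets)
    if views is None:
        return 0.0
    s = sum(v.astype(np.int32) for v in views)
    if fam.order == 2:
        v = V.pair_eq[fam.family_id]
        n_eq = np.count_nonzero((s == 0) | (s == 2))
        return v * n_eq - v * (s.size - n_eq)
    if fam.order == 3:
        v = V.triple_eq3[fam.family_id]
        n_eq3 = np.count_nonzero((s == 0) | (s == 3))
        return v * n_eq3 - v * (s.size - n_eq3)
    v4, v3, v2 = V.quad[fam.family_id]
    n4 = np.count_nonzero((s == 0) | (s == 4))
    n3 = np.count_nonzero((s == 1) | (s == 3))
    n2 = np.count_nonzero(s == 2)
    return v4 * n4 + v3 * n3 + v2 * n2


def gibbs_energy(m: RegionMap | np.ndarray, V: GibbsPotentials,
                 families: Sequence[CliqueFamily] | None = None) -> float:
    """Unnormalized Gibbs exponent: sum of potentials over all cliques."""
    labels = m.labels if isinstance(m, RegionMap) else np.asarray(m)
    labels = labels.astype(np.int8)
    families = default_families() if families is None else families
    return float(sum(_clique_potential_sums(labels, fam, V) for fam in families))


def spatial_probability_volume(m: RegionMap | np.ndarray, V: GibbsPotentials,
                               families: Sequence[CliqueFamily] | None = None,
                               ) -> np.ndarray:
    """Voxel-wise conditional kidney probability ``Pr_V:p(1)`` for the map.

    For each voxel the energies of both label assignments (all other labels
    fixed from ``m``) differ by a sum over the cliques containing the voxel;
    the conditional probability is the two-state softmax of that difference.
    Cliques crossing the lattice boundary are skipped.
    """
    labels = m.labels if isinstance(m, RegionMap) else np.asarray(m)
    labels = labels.astype(np.int8)
    families = default_families() if families is None else families
    delta = np.zeros(labels.shape, dtype=np.float64)

    for fam in families:
        k = len(fam.offsets)
        for role in range(k):
            # clique containing p with p playing offset[role]:
            # other voxels sit at offsets[j] - offsets[role]
            rel = [
                tuple(o - r for o, r in zip(fam.offsets[j], fam.offsets[role]))
                for j in range(k)
            ]
            views = _shifted_views(labels, rel)
            if views is None:
                continue
            others = sum(
                views[j].astype(np.int32) for j in range(k) if j != role
            )
            if fam.order == 2:
                v = V.pair_eq[fam.family_id]
                # other label n: dE = V(eq for l=1) - V for l=0 = 2v(2n-1)
                contrib = 2.0 * v * (2 * others - 1)
            elif fam.order == 3:
                v = V.triple_eq3[fam.family_id]
                # all-equal only when both others share the candidate label
                contrib = 2.0 * v * ((others == 2).astype(np.float64)
                                     - (others == 0).astype(np.float64))
            else:
                v4, v3, v2 = V.quad[fam.family_id]
                # others sum s3 in {0..3}; dE = V[class(s3+1)] - V[class(s3)]
                table = np.array(
                    [v3 - v4, v2 - v3, v3 - v2, v4 - v3], dtype=np.float64
                )
                contrib = table[others]
            # scatter-add into the anchor positions of this role
            lo = [max(0, -min(off[ax] for off in rel)) for ax in range(3)]
            hi = [labels.shape[ax] - max(0, max(off[ax] for off in rel))
                  for ax in range(3)]
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            delta[sl] += contrib
    return expit(delta)


def spatial_label_probability(m: RegionMap | np.ndarray, V: GibbsPotentials,
                              p: tuple[int, int, int], l: int,
                              families: Sequence[CliqueFamily] | None = None,
                              ) -> float:
    """Conditional Gibbs probability of label ``l`` at voxel ``p``."""
    labels = m.labels if isinstance(m, RegionMap) else np.asarray(m)
    if not all(0 <= c < n for c, n in zip(p, labels.shape)):
        raise IndexError(f"voxel {p} outside the lattice")
    pr1 = spatial_probability_volume(labels, V, families)[p]
    return float(pr1 if l == 1 else 1.0 - pr1)


def gibbs_sample(V: GibbsPotentials, dims: tuple[int, int, int],
                 n_sweeps: int = 50, seed: int = 0,
                 families: Sequence[CliqueFamily] | None = None,
                 init: np.ndarray | None = None) -> RegionMap:
    """Gibbs sampler over region maps, deterministic given the seed.

    Single-site conditional updates applied on a 27-colour chromatic
    schedule (period 3 per axis), so that simultaneously updated sites never
    share a clique; one sweep updates every site exactly once.
    """
    if min(dims) < 8:
        raise ValueError("sampler needs dims >= 8 in every axis")
    families = default_families() if families is None else families
    rng = np.random.default_rng(seed)
    labels = (
        (rng.random(dims) < 0.5).astype(np.int8)
        if init is None else np.asarray(init, dtype=np.int8).copy()
    )
    colors = [
        (cx, cy, cz) for cx in range(3) for cy in range(3) for cz in range(3)
    ]
    for _ in range(n_sweeps):
        for cx, cy, cz in colors:
            pr1 = spatial_probability_volume(labels, V, families)
            sel = np.zeros(dims, dtype=bool)
            sel[cx::3, cy::3, cz::3] = True
            u = rng.random(dims)
            labels[sel] = (u[sel] < pr1[sel]).astype(np.int8)
    return RegionMap(labels.astype(np.uint8))
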