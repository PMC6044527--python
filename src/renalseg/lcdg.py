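"""First-order appearance model: linear combination of discrete Gaussians.

The empirical marginal distribution of gray levels is approximated by a
signed mixture with exactly two positive *dominant* discrete Gaussians (one
per class: kidney and background) plus sign-alternating *subordinate*
components that absorb the residual deviations.  The fitted mixture is then
split into two per-class submodels ``Pr(q|l)``, ``l in {0, 1}``, and a
gray-level threshold where the weighted submodels cross.

A discrete Gaussian on ``{0..Q-1}`` is defined by Gaussian CDF differences
at half-integer bin boundaries, renormalized to sum to one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorized

from .io_volumes import RegionMap, Volume

__all__ = [
    "Histogram",
    "DiscreteGaussian",
    "LCDGComponent",
    "LCDGModel",
    "ClassSubmodels",
    "build_histogram",
    "fit_dominant",
    "fit_lcdg",
    "split_classes",
    "class_likelihood",
]

SIGMA_FLOOR = 0.5  # gray levels; spike histograms hit this lower bound


@dataclass
class Histogram:
    """Relative gray-level frequencies over {0..Q-1}."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.ndim != 1 or np.any(self.freqs < 0):
            raise ValueError("histogram must be a 1D non-negative array")
        total = self.freqs.sum()
        if total > 0:
            self.freqs = self.freqs / total

    @property
    def q_levels(self) -> int:
        return self.freqs.size

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.q_levels)


@dataclass
class DiscreteGaussian:
    """A Gaussian discretized onto the gray-level set."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        self.std = max(float(self.std), SIGMA_FLOOR)

    def pmf(self, q_levels: int) -> np.ndarray:
        """CDF differences at half-integer boundaries, renormalized."""
        edges = np.arange(q_levels + 1) - 0.5
        cdf = ndtr((edges - self.mean) / self.std)
        p = np.diff(cdf)
        total = p.sum()
        if total <= 0:  # mean far outside the range; fall back to nearest spike
            p = np.zeros(q_levels)
            p[int(np.clip(round(self.mean), 0, q_levels - 1))] = 1.0
            return p
        return p / total


@dataclass
class LCDGComponent:
    weight: float
    gaussian: DiscreteGaussian
    dominant: bool = False
    label: int | None = None  # 0 background, 1 kidney; set for dominants / after split


@dataclass
class LCDGModel:
    """Signed mixture: 2 positive dominant components + subordinates."""

    components: list[LCDGComponent]
    q_levels: int = 256
    converged: bool = True

    @property
    def dominant(self) -> list[LCDGComponent]:
        return [c for c in self.components if c.dominant]

    @property
    def subordinate(self) -> list[LCDGComponent]:
        return [c for c in self.components if not c.dominant]

    def density(self, clip: bool = True) -> np.ndarray:
        p = np.zeros(self.q_levels)
        for c in self.components:
            p = p + c.weight * c.gaussian.pmf(self.q_levels)
        return np.maximum(p, 0.0) if clip else p

    def l1_error(self, h: Histogram) -> float:
        return float(np.abs(self.density() - h.freqs).sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "q_levels": self.q_levels,
                "converged": self.converged,
                "components": [
                    {
                        "weight": c.weight,
                        "mean": c.gaussian.mean,
                        "std": c.gaussian.std,
                        "dominant": c.dominant,
                        "label": c.label,
                    }
                    for c in self.components
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LCDGModel":
        obj = json.loads(text)
        comps = [
            LCDGComponent(
                weight=c["weight"],
                gaussian=DiscreteGaussian(c["mean"], c["std"]),
                dominant=c["dominant"],
                label=c["label"],
            )
            for c in obj["components"]
        ]
        return cls(comps, q_levels=obj["q_levels"], converged=obj["converged"])


def build_histogram(v: Volume, mask: RegionMap | None = None) -> Histogram:
    """Relative frequencies of gray levels, optionally restricted to a mask."""
    if mask is None:
        values = v.data.ravel()
    else:
        sel = mask.labels.astype(bool)
        if not sel.any():
            raise ValueError("empty mask")
        values = v.data[sel]
    counts = np.bincount(values, minlength=v.q_levels)
    return Histogram(counts)


def _em_two_component(h: Histogram, max_iter: int = 300, tol: float = 1e-9,
                      ) -> list[LCDGComponent]:
    """EM for a 2-component discrete-Gaussian mixture on a histogram."""
    q = h.levels.astype(np.float64)
    w = h.freqs
    # moment-based initialization: split at the weighted median
    cdf = np.cumsum(w)
    split = int(np.searchsorted(cdf, 0.5))
    parts = []
    for sel in (q <= split, q > split):
        mass = w[sel].sum()
        if mass <= 0:
            mass = 1e-12
        mu = float((w[sel] * q[sel]).sum() / mass)
        var = float((w[sel] * (q[sel] - mu) ** 2).sum() / mass)
        parts.append([mass, mu, max(np.sqrt(var), SIGMA_FLOOR)])

    prev_ll = -np.inf
    for _ in range(max_iter):
        pmfs = np.stack(
            [pi * DiscreteGaussian(mu, sd).pmf(h.q_levels) for pi, mu, sd in parts]
        )
        total = pmfs.sum(axis=0)
        total = np.maximum(total, 1e-300)
        resp = pmfs / total
        ll = float((w * np.log(total)).sum())
        for k in range(2):
            mass = float((w * resp[k]).sum())
            if mass <= 1e-12:
                continue
            mu = float((w * resp[k] * q).sum() / mass)
            var = float((w * resp[k] * (q - mu) ** 2).sum() / mass)
            parts[k] = [mass, mu, max(np.sqrt(var), SIGMA_FLOOR)]
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    total_mass = sum(p[0] for p in parts)
    return [
        LCDGComponent(p[0] / total_mass, DiscreteGaussian(p[1], p[2]), dominant=True)
        for p in parts
    ]


def fit_dominant(h: Histogram, kidney_brighter: bool = True) -> LCDGModel:
    """Fit the two positive dominant components by EM.

    The lower-mean component is assigned the background label by default
    (``kidney_brighter=True``); the assignment is configurable because the
    kidney/background brightness ordering flips with b-value and protocol.
    """
    occupied = np.count_nonzero(h.freqs)
    if occupied < 2:
        raise ValueError("histogram has fewer than 2 occupied gray levels")
    comps = _em_two_component(h)
    comps.sort(key=lambda c: c.gaussian.mean)
    lo, hi = comps
    lo.label, hi.label = (0, 1) if kidney_brighter else (1, 0)
    return LCDGModel(comps, q_levels=h.q_levels)


def _residual_component(resid: np.ndarray) -> tuple[float, DiscreteGaussian]:
    """Fit one signed component to the largest contiguous residual mode."""
    q0 = int(np.argmax(np.abs(resid)))
    sign = np.sign(resid[q0])
    same = np.sign(resid) == sign
    # contiguous run of same-signed residual around the peak
    left = q0
    while left > 0 and same[left - 1]:
        left -= 1
    right = q0
    while right < resid.size - 1 and same[right + 1]:
        right += 1
    region = np.arange(left, right + 1)
    r = np.abs(resid[region])
    mass = r.sum()
    mu = float((r * region).sum() / mass)
    var = float((r * (region - mu) ** 2).sum() / mass)
    weight = float(sign * mass)
    return weight, DiscreteGaussian(mu, np.sqrt(var))


def fit_lcdg(h: Histogram, max_subordinate: int = 8, tol: float = 1e-4,
             kidney_brighter: bool = True, max_refine: int = 50) -> LCDGModel:
    """Full LCDG fit: dominant mixture plus sign-alternate subordinates.

    Subordinate components are added greedily from the largest mode of the
    residual (empirical minus current model), each weighted with the residual
    sign; a component is kept only if it reduces the L1 fit error by more
    than ``tol``.  Negative weights are limited so the total mixture density
    stays non-negative at every gray level.  A final refinement pass
    re-solves all component weights by non-negativity-constrained projected
    least squares (the modified-EM weight update).
    """
    model = fit_dominant(h, kidney_brighter=kidney_brighter)
    best_err = model.l1_error(h)
    for _ in range(max_subordinate):
        resid = h.freqs - model.density(clip=False)
        if np.abs(resid).sum() <= tol:
            break
        weight, g = _residual_component(resid)
        pmf = g.pmf(h.q_levels)
        if weight < 0:
            # cap the negative weight so the signed density stays >= 0
            dens = model.density(clip=False)
            pos = pmf > 1e-12
            cap = -np.min(dens[pos] / pmf[pos]) if pos.any() else 0.0
            weight = max(weight, cap)
        cand = LCDGModel(
            model.components + [LCDGComponent(weight, g)], q_levels=h.q_levels
        )
        err = cand.l1_error(h)
        if err >= best_err - tol:
            break
        model, best_err = cand, err

    refined = _refine_weights(model, h, max_refine)
    if refined.l1_error(h) <= best_err:
        model = refined
    if len(model.subordinate) >= max_subordinate and model.l1_error(h) > tol:
        model.converged = False
        warnings.warn("LCDG fit hit the subordinate budget before tolerance")
    # weights over the whole model sum to 1 (the density then sums to ~1)
    total = sum(c.weight for c in model.components)
    if total > 0:
        for c in model.components:
            c.weight /= total
    return model


def _refine_weights(model: LCDGModel, h: Histogram, max_iter: int) -> LCDGModel:
    """Projected-gradient least-squares on the component weights.

    Dominant weights are kept positive; subordinate weights keep their sign
    but may shrink; the mixture density is kept non-negative by a final
    feasibility backtrack.
    """
    pmfs = np.stack([c.gaussian.pmf(model.q_levels) for c in model.components])
    w = np.array([c.weight for c in model.components])
    target = h.freqs
    step = 1.0 / max(np.sum(pmfs**2), 1e-12)
    for _ in range(max_iter):
        resid = target - w @ pmfs
        grad = pmfs @ resid
        w_new = w + step * grad
        w_new[0] = max(w_new[0], 1e-6)
        w_new[1] = max(w_new[1], 1e-6)
        # keep density non-negative: backtrack toward the previous feasible w
        for _bt in range(20):
            if np.all(w_new @ pmfs >= -1e-12):
                break
            w_new = 0.5 * (w_new + w)
        if np.abs(w_new - w).max() < 1e-12:
            w = w_new
            break
        w = w_new
    comps = [
        LCDGComponent(float(wk), c.gaussian, dominant=c.dominant, label=c.label)
        for wk, c in zip(w, model.components)
    ]
    return LCDGModel(comps, q_levels=model.q_levels, converged=model.converged)


@dataclass
class ClassSubmodels:
    """Per-class gray-level likelihoods ``Pr(q|l)`` and the crossing threshold."""

    pr: np.ndarray  # shape (2, Q); rows are labels 0 (background), 1 (kidney)
    class_weights: np.ndarray  # prior mixture mass of each class
    threshold: int
    crossing_found: bool = True

    def likelihood(self, q, l: int) -> np.ndarray | float:
        return self.pr[l][q]


def split_classes(model: LCDGModel) -> ClassSubmodels:
    """Split the fitted LCDG into kidney/background submodels.

    Each subordinate component joins the dominant class whose submodel it
    improves, chosen greedily to minimize the overlap between the two
    weighted class submodels.  Submodels are clipped to non-negative and
    renormalized; the threshold ``t*`` is the gray level where the weighted
    submodels cross between the dominant means.
    """
    doms = model.dominant
    if len(doms) != 2 or any(d.label is None for d in doms):
        raise ValueError("model must carry two labelled dominant components")
    q_levels = model.q_levels
    by_label: dict[int, list[LCDGComponent]] = {0: [], 1: []}
    for d in doms:
        by_label[d.label].append(d)

    def class_density(comps: list[LCDGComponent]) -> np.ndarray:
        p = np.zeros(q_levels)
        for c in comps:
            p = p + c.weight * c.gaussian.pmf(q_levels)
        return p

    for sub in model.subordinate:
        overlaps = []
        for lab in (0, 1):
            trial = {l: list(cs) for l, cs in by_label.items()}
            trial[lab].append(sub)
            d0 = np.maximum(class_density(trial[0]), 0)
            d1 = np.maximum(class_density(trial[1]), 0)
            overlaps.append(np.minimum(d0, d1).sum())
        lab = int(np.argmin(overlaps))
        sub.label = lab
        by_label[lab].append(sub)

    weighted = np.zeros((2, q_levels))
    class_w = np.zeros(2)
    for lab in (0, 1):
        weighted[lab] = np.maximum(class_density(by_label[lab]), 0.0)
        class_w[lab] = weighted[lab].sum()
    pr = np.zeros_like(weighted)
    for lab in (0, 1):
        pr[lab] = weighted[lab] / class_w[lab] if class_w[lab] > 0 else weighted[lab]
    class_w = class_w / max(class_w.sum(), 1e-300)

    means = sorted(d.gaussian.mean for d in doms)
    mlo, mhi = int(round(means[0])), int(round(means[1]))
    mlo, mhi = max(mlo, 0), min(mhi, q_levels - 1)
    diff = class_w[1] * pr[1] - class_w[0] * pr[0]
    threshold, found = None, True
    crossings = [
        t for t in range(mlo, mhi)
        if (diff[t] <= 0 < diff[t + 1]) or (diff[t] >= 0 > diff[t + 1])
    ]
    if crossings:
        mid = 0.5 * (mlo + mhi)
        threshold = min(crossings, key=lambda t: abs(t - mid))
    else:
        threshold = int(round(0.5 * (means[0] + means[1])))
        found = False
        warnings.warn("no submodel crossing between dominant means; using midpoint")
    return ClassSubmodels(pr=pr, class_weights=class_w, threshold=threshold,
                          crossing_found=found)


def class_likelihood(submodels: ClassSubmodels, q, l: int):
    """``Pr(q|l)`` for gray level(s) ``q`` and label ``l``."""
    return submodels.likelihood(q, l)
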