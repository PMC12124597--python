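"""Coherence-based structural prior from random detector subsets.

True absorbers reconstruct consistently no matter which detector elements
are used, while streak artifacts and noise fluctuate with the detection
configuration. The prior exploits this: k images R_1..R_k are reconstructed
from random s-element subsets (s < N) and combined pixelwise into a
coherence map

    D = (R_1 + ... + R_k)^2 / (k * (R_1^2 + ... + R_k^2)),

which lies in [0, 1] by Cauchy-Schwarz and equals 1 exactly where all
subset values agree and are nonzero. D is then sharpened by a global
Gaussian-CDF weighting,

    P = D * integral_{vmin}^{D} Phi(v | mu, sigma) dv,

with vmin = min D, vmax = max D, mu = (vmax + vmin)/2 and
sigma = (vmax - vmin)/6, and min-max normalized to Pnorm in [0, 1]. The
weighting pushes the map toward the extremes 0 and 1: strong coherent
regions are emphasized, weak ones suppressed but not discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from .forward import ChannelData
from .geometry import ImageGrid
from .recon import ReconImage, ubp_filter, _backproject

__all__ = [
    "SubsetPlan",
    "CoherenceMap",
    "ProbabilityMap",
    "make_subset_plan",
    "coherence_map",
    "gaussian_cdf",
    "prior_integral",
    "probability_map",
    "build_prior",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsetPlan:
    """k random s-element subsets of an N-element array, seeded."""

    subsets: tuple[tuple[int, ...], ...]
    n_elements: int
    seed: int

    @property
    def k(self) -> int:
        return len(self.subsets)

    @property
    def s(self) -> int:
        return len(self.subsets[0])

    def to_dict(self) -> dict:
        return {
            "n_elements": self.n_elements,
            "s": self.s,
            "k": self.k,
            "seed": self.seed,
            "subsets": [list(sub) for sub in self.subsets],
        }


def make_subset_plan(
    n_elements: int, s: int, k: int, seed: int, disjoint: bool = False
) -> SubsetPlan:
    """Draw k subsets of s distinct element indices each.

    By default subsets are drawn independently (uniformly without
    replacement within a subset; overlap across subsets allowed). With
    ``disjoint=True`` the subsets partition a random permutation of the
    elements instead, which requires ``s * k <= n_elements``.

    A sensible default for s is about one tenth of the total element count.
    """
    if not 2 <= s < n_elements:
        raise ValueError(f"need 2 <= s < N, got s={s}, N={n_elements}")
    if k < 2:
        raise ValueError("need at least k=2 subsets")
    rng = np.random.default_rng(seed)
    if disjoint:
        if s * k > n_elements:
            raise ValueError("disjoint plan requires s*k <= N")
        perm = rng.permutation(n_elements)
        subsets = tuple(
            tuple(int(i) for i in sorted(perm[j * s : (j + 1) * s])) for j in range(k)
        )
    else:
        subsets = tuple(
            tuple(int(i) for i in sorted(rng.choice(n_elements, size=s, replace=False)))
            for _ in range(k)
        )
    return SubsetPlan(subsets, n_elements, seed)


@dataclass(frozen=True)
class CoherenceMap:
    """Pixelwise subset-agreement score D with its global statistics."""

    grid: ImageGrid
    D: np.ndarray
    vmin: float
    vmax: float
    mu: float
    sigma: float


def coherence_map(subset_images: list[ReconImage]) -> CoherenceMap:
    """Pixelwise coherence of k subset reconstructions.

    Pixels where all subset values are zero carry no signal and get D = 0.
    """
    if len(subset_images) < 2:
        raise ValueError("need at least 2 subset images")
    grid = subset_images[0].grid
    for im in subset_images[1:]:
        if im.grid.shape != grid.shape or im.grid.spacing != grid.spacing:
            raise ValueError("all subset images must share one grid")
    stack = np.stack([im.values for im in subset_images])
    k = stack.shape[0]
    num = stack.sum(axis=0) ** 2
    den = k * (stack**2).sum(axis=0)
    D = np.zeros(grid.shape)
    np.divide(num, den, out=D, where=den > 0)
    # guard against floating-point overshoot of the Cauchy-Schwarz bound
    np.clip(D, 0.0, 1.0, out=D)
    # equality holds exactly where all subset values agree and are nonzero;
    # assign it directly so rounding in the ratio cannot blur the bound
    all_equal = (stack.max(axis=0) == stack.min(axis=0)) & (stack[0] != 0)
    D[all_equal] = 1.0
    vmin, vmax = float(D.min()), float(D.max())
    mu = (vmax + vmin) / 2.0
    sigma = (vmax - vmin) / 6.0
    return CoherenceMap(grid, D, vmin, vmax, mu, sigma)


def gaussian_cdf(v, mu: float, sigma: float):
    """Normal CDF Phi(v | mu, sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return special.ndtr((np.asarray(v, dtype=float) - mu) / sigma)


def _phi_antiderivative(v, mu: float, sigma: float):
    """Antiderivative of Phi(v|mu,sigma): sigma*(z*Phi01(z) + phi01(z)), z=(v-mu)/sigma."""
    z = (np.asarray(v, dtype=float) - mu) / sigma
    return sigma * (z * special.ndtr(z) + np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi))


def prior_integral(d, vmin: float, vmax: float, mu: float, sigma: float):
    """Closed form of ``integral_{vmin}^{min(d, vmax)} Phi(v | mu, sigma) dv``.

    This is the Gaussian-CDF weighting factor applied to each coherence
    value d; the unit step in the integrand truncates the integral at d
    (upper limit inclusive, u(0) = 1 — a measure-zero convention fixed for
    determinism).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive (handle vmax == vmin upstream)")
    d = np.asarray(d, dtype=float)
    if np.any(d < vmin - 1e-12) or np.any(d > vmax + 1e-12):
        raise ValueError("d must lie within [vmin, vmax]")
    upper = np.minimum(d, vmax)
    out = _phi_antiderivative(upper, mu, sigma) - _phi_antiderivative(vmin, mu, sigma)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ProbabilityMap:
    """Structural prior: raw P and its min-max normalization Pnorm in [0, 1]."""

    grid: ImageGrid
    P: np.ndarray
    Pnorm: np.ndarray


def probability_map(coh: CoherenceMap) -> ProbabilityMap:
    """Weight the coherence map and min-max normalize it to [0, 1].

    Degenerate constant-P fields (including constant D, where the Gaussian
    scale collapses) yield the non-informative prior Pnorm = 1 everywhere,
    so that the regularizer suppresses nothing.
    """
    if coh.sigma <= 0:
        # constant D: no spread to weight against
        P = np.zeros(coh.grid.shape)
    else:
        P = coh.D * prior_integral(coh.D, coh.vmin, coh.vmax, coh.mu, coh.sigma)
    pmin, pmax = float(P.min()), float(P.max())
    if pmax - pmin <= 0:
        logger.warning(
            "probability map is constant; using the non-informative prior Pnorm=1"
        )
        pnorm = np.ones(coh.grid.shape)
    else:
        pnorm = (P - pmin) / (pmax - pmin)
    return ProbabilityMap(coh.grid, P, pnorm)


def build_prior(
    data: ChannelData,
    grid: ImageGrid,
    plan: SubsetPlan,
    algo: str = "ubp",
) -> ProbabilityMap:
    """Reconstruct every planned subset and assemble the structural prior."""
    if plan.n_elements != data.n_elements:
        raise ValueError(
            f"plan is for N={plan.n_elements} elements but data has N={data.n_elements}"
        )
    if algo not in ("das", "ubp"):
        raise ValueError("algo must be 'das' or 'ubp'")
    src = ubp_filter(data) if algo == "ubp" else data
    # back-project each element once; a subset image is the mean of its
    # elements' single-element back-projections (exact, by linearity)
    per_element = np.stack(
        [_backproject(src, grid, np.array([d])).ravel() for d in range(data.n_elements)]
    )
    images = [
        ReconImage(
            grid,
            per_element[list(sub)].mean(axis=0).reshape(grid.shape),
            provenance=f"{algo} subset {i}",
        )
        for i, sub in enumerate(plan.subsets)
    ]
    return probability_map(coherence_map(images))
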