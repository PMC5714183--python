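"""Shared domain types.

The package models polymorphism and divergence at coding sites under the
joint action of selection (a distribution of fitness effects, DFE) and
GC-biased gene conversion (gBGC).  Mutations are grouped into three classes
by their base change: WWSS (A<->T, C<->G; unaffected by gBGC), W->S (A/T ->
G/C; favoured with strength ``B``) and S->W (disfavoured with strength
``-B``), where ``B = 4Nb`` is the scaled conversion-bias coefficient.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MutationClass",
    "SiteClass",
    "DFEModel",
    "GBGCContext",
    "ClassSFS",
    "DivergenceSummary",
    "TwoEpochDemography",
    "SummaryStats",
    "NesBinProportions",
    "AdaptiveRateEstimate",
]


class MutationClass(enum.Enum):
    """Base-change class of a mutation with respect to gBGC."""

    WWSS = "WWSS"
    WS = "WS"
    SW = "SW"
    COMBINED = "COMBINED"
    #: unpolarized W<->S change (polymorphism data cannot split WS from SW)
    WS_OR_SW = "WS_OR_SW"


class SiteClass(enum.Enum):
    """Functional class of a site."""

    FOURFOLD = "fourfold"
    ZEROFOLD = "zerofold"
    UTR = "utr"


@dataclass(frozen=True)
class DFEModel:
    """Distribution of fitness effects of new mutations.

    The deleterious part is a reflected gamma distribution: ``-gamma ~
    Gamma(shape_beta, mean=-mean_gamma)`` on the scaled-coefficient axis
    ``gamma = 4Ns``.  Optionally a fraction ``beneficial_fraction`` of new
    mutations is beneficial with a single coefficient ``beneficial_gamma``.

    Parameters
    ----------
    shape_beta
        Gamma shape parameter (beta > 0).
    mean_gamma
        Mean of the deleterious scaled coefficient (<= 0).
    beneficial_fraction
        Proportion of new mutations that are beneficial, in [0, 1].
    beneficial_gamma
        Scaled coefficient of the beneficial point mass (> 0 when used).
    """

    shape_beta: float
    mean_gamma: float
    beneficial_fraction: float = 0.0
    beneficial_gamma: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.shape_beta) or self.shape_beta <= 0:
            raise ValueError(f"shape_beta must be > 0, got {self.shape_beta}")
        if not np.isfinite(self.mean_gamma) or self.mean_gamma > 0:
            raise ValueError(f"mean_gamma must be <= 0, got {self.mean_gamma}")
        if not 0.0 <= self.beneficial_fraction <= 1.0:
            raise ValueError("beneficial_fraction must lie in [0, 1]")
        if self.beneficial_fraction > 0 and self.beneficial_gamma <= 0:
            raise ValueError(
                "beneficial_gamma must be > 0 when beneficial_fraction > 0"
            )

    @property
    def mean_abs_gamma(self) -> float:
        """|mean_gamma| of the deleterious part."""
        return -self.mean_gamma

    @property
    def gamma_scale(self) -> float:
        """Scale parameter of the gamma distribution on |gamma|."""
        if self.mean_gamma == 0.0:
            return 0.0
        return self.mean_abs_gamma / self.shape_beta

    def deleterious_quadrature(self, n_nodes: int = 256):
        """Quadrature nodes/weights for expectations over the deleterious part.

        Composite Gauss-Legendre on log |gamma| between 1e-8 and the
        1 - 1e-14 quantile; the probability mass below 1e-8 (effectively
        neutral) is carried by an explicit node at gamma = 0.  Returns
        ``(gamma_nodes, weights)`` with ``gamma_nodes <= 0`` and weights
        summing to 1 (to ~1e-14).  A point mass at 0 (``mean_gamma == 0``)
        collapses to a single node.
        """
        from scipy import stats

        if self.mean_gamma == 0.0:
            return np.zeros(1), np.ones(1)
        beta, scale = self.shape_beta, self.gamma_scale
        s_min = 1e-8
        s_max = stats.gamma.ppf(1.0 - 1e-14, a=beta, scale=scale)
        per = 16
        n_panels = max(1, n_nodes // per)
        edges = np.linspace(np.log(s_min), np.log(s_max), n_panels + 1)
        xs, ws = np.polynomial.legendre.leggauss(per)
        y = np.concatenate(
            [0.5 * (b - a) * xs + 0.5 * (a + b) for a, b in zip(edges[:-1], edges[1:])]
        )
        w = np.concatenate(
            [0.5 * (b - a) * ws for a, b in zip(edges[:-1], edges[1:])]
        )
        s = np.exp(y)
        weights = w * stats.gamma.pdf(s, a=beta, scale=scale) * s
        mass_below = stats.gamma.cdf(s_min, a=beta, scale=scale)
        return (
            np.concatenate(([0.0], -s)),
            np.concatenate(([mass_below], weights)),
        )


@dataclass(frozen=True)
class GBGCContext:
    """Population/mutation context for the gBGC model.

    Attributes
    ----------
    B
        Scaled gBGC coefficient 4Nb (>= 0).
    kappa
        Mutational bias: the GC->AT rate is ``kappa`` times the AT->GC rate.
    gc_content
        Equilibrium GC content p, in (0, 1); assumed constant in time.
    theta
        Scaled mutation rate 4Nu per site.
    sample_size
        Number of sampled chromosomes n (>= 2).
    """

    B: float
    kappa: float
    gc_content: float
    theta: float
    sample_size: int

    def __post_init__(self) -> None:
        if self.B < 0 or not np.isfinite(self.B):
            raise ValueError("B must be finite and >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if int(self.sample_size) != self.sample_size or self.sample_size < 2:
            raise ValueError("sample_size must be an integer >= 2")

    def class_weight(self, cls: MutationClass) -> float:
        """Relative mutational input of a class: theta, (1-p)theta, p*kappa*theta."""
        p = self.gc_content
        if cls is MutationClass.WWSS:
            return self.theta
        if cls is MutationClass.WS:
            return (1.0 - p) * self.theta
        if cls is MutationClass.SW:
            return p * self.kappa * self.theta
        raise ValueError(f"no mutational weight for class {cls}")

    def class_shift(self, cls: MutationClass) -> float:
        """Additive gBGC shift of the scaled coefficient: 0, +B or -B."""
        if cls is MutationClass.WWSS:
            return 0.0
        if cls is MutationClass.WS:
            return self.B
        if cls is MutationClass.SW:
            return -self.B
        raise ValueError(f"no gBGC shift for class {cls}")


@dataclass
class ClassSFS:
    """A site-frequency spectrum for one mutation class.

    ``entries[k]`` is the expected (or observed) count for frequency class
    ``i = k + 1``.  Unfolded spectra have length ``n - 1``; folded spectra
    length ``n // 2`` (minor-allele classes).
    """

    cls: MutationClass
    entries: np.ndarray
    sample_size: int
    folded: bool = False
    site_count: float = 1.0

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = self.sample_size
        expected = n // 2 if self.folded else n - 1
        if self.entries.shape != (expected,):
            raise ValueError(
                f"SFS length {self.entries.shape} inconsistent with n={n}, "
                f"folded={self.folded} (expected {expected})"
            )
        if np.any(self.entries < 0):
            raise ValueError("SFS entries must be nonnegative")
        if self.site_count < 0:
            raise ValueError("site_count must be nonnegative")

    @property
    def n_segregating(self) -> float:
        return float(self.entries.sum())

    def scaled(self, n_sites: float) -> "ClassSFS":
        """Return a copy with entries multiplied by ``n_sites``."""
        return ClassSFS(
            cls=self.cls,
            entries=self.entries * n_sites,
            sample_size=self.sample_size,
            folded=self.folded,
            site_count=n_sites,
        )


@dataclass(frozen=True)
class DivergenceSummary:
    """Expected divergence per mutation class (model scale ``t_theta = T*theta``)."""

    k_wwss: float
    k_ws: float
    k_sw: float
    t_theta: float

    @property
    def k_total(self) -> float:
        return self.k_wwss + self.k_ws + self.k_sw


@dataclass(frozen=True)
class TwoEpochDemography:
    """Single step change in population size, from N1 to N2 = size_ratio * N1.

    ``change_time`` is the age of the change in units of 2*N2 generations.
    ``size_ratio == 1`` reduces to the constant-size model (``change_time``
    is then immaterial).
    """

    size_ratio: float
    change_time: float
    ancestral_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.size_ratio <= 0:
            raise ValueError("size_ratio must be > 0")
        if self.change_time < 0:
            raise ValueError("change_time must be >= 0")
        if self.ancestral_scale <= 0:
            raise ValueError("ancestral_scale must be > 0")


@dataclass(frozen=True)
class SummaryStats:
    """Per-class polymorphism summaries (per-site pi and theta_W)."""

    pi: float
    watterson_theta: float
    tajimas_d: Optional[float]
    n_sites: int
    n_segregating: int


@dataclass(frozen=True)
class NesBinProportions:
    """Proportions of new mutations by strength of purifying selection."""

    nearly_neutral: float
    intermediate: float
    strong: float

    def __post_init__(self) -> None:
        total = self.nearly_neutral + self.intermediate + self.strong
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"bin proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class AdaptiveRateEstimate:
    """Point estimates and bootstrap CIs for alpha and omega_a."""

    alpha: float
    omega_a: float
    alpha_ci: tuple = field(default=(np.nan, np.nan))
    omega_a_ci: tuple = field(default=(np.nan, np.nan))
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        if self.alpha > 1.0 + 1e-12:
            raise ValueError("alpha cannot exceed 1")
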