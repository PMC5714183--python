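"""Poisson-random-field expectations under selection and gBGC.

Closed-form/quadrature evaluation of the expected site-frequency spectrum
(SFS) and divergence for the three mutation classes, and the analytic
"true" proportion (alpha) and relative rate (omega_a) of adaptive
substitution.

Model
-----
For a mutation with scaled coefficient ``gamma = 4Ns`` segregating at
population frequency ``x``, the expected contribution to sample frequency
class ``i`` of an ``n``-chromosome sample is

    tau(gamma, x, i) = [1 - exp(-gamma (1-x))] / [(1 - exp(-gamma)) x (1-x)]
                       * C(n, i) x^i (1-x)^(n-i)

and the expected SFS of a class is the mutational weight of the class times
the double integral of ``tau`` over ``x`` in (0, 1) and over the DFE, with
the class gBGC shift (0, +B or -B) added to ``gamma``.  Divergence uses the
fixation-rate ratio ``u(gamma) = gamma / (1 - exp(-gamma))`` in the same
way.  gBGC and selection are assumed to combine additively, and the GC
content is treated as constant in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import ClassSFS, DFEModel, DivergenceSummary, GBGCContext, MutationClass

__all__ = [
    "QuadratureConfig",
    "QuadratureError",
    "fixation_rate_ratio",
    "sfs_integrand",
    "expected_class_sfs",
    "combined_sfs",
    "fold_sfs",
    "expected_divergence",
    "true_alpha",
    "true_omega_a",
]


class QuadratureError(RuntimeError):
    """Raised when doubling the quadrature grids does not confirm convergence."""


@dataclass(frozen=True)
class QuadratureConfig:
    """Grid sizes and convergence tolerance for the double quadrature."""

    x_nodes: int = 256
    gamma_nodes: int = 256
    tol: float = 1e-6
    check_convergence: bool = False


_DEFAULT_QUAD = QuadratureConfig()

_SELECTED_CLASSES = (MutationClass.WWSS, MutationClass.WS, MutationClass.SW)


def fixation_rate_ratio(gamma):
    """Fixation rate relative to neutral, u(gamma) = gamma / (1 - e^-gamma).

    Continuous at 0 with u(0) = 1.  Evaluated in overflow-safe form on both
    tails: for gamma < 0 the equivalent ``gamma e^gamma / (e^gamma - 1)`` is
    used, so u(-2000) underflows gracefully to 0 instead of overflowing.
    Accepts scalars or arrays.
    """
    g = np.asarray(gamma, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("fixation_rate_ratio requires finite gamma")
    out = np.ones_like(g)
    pos = g > 0
    neg = g < 0
    with np.errstate(over="ignore"):
        out[pos] = g[pos] / (-np.expm1(-g[pos]))
        out[neg] = g[neg] * np.exp(g[neg]) / np.expm1(g[neg])
    if np.isscalar(gamma) or np.ndim(gamma) == 0:
        return float(out)
    return out


def _tau_ratio(gamma: float, x: np.ndarray) -> np.ndarray:
    """(1 - e^{-gamma(1-x)}) / (1 - e^{-gamma}), stable for large |gamma|.

    For gamma < 0 both numerator and denominator are rewritten after
    multiplying through by e^{gamma}, so only exponentials of negative
    arguments appear.
    """
    if gamma == 0.0:
        return 1.0 - x  # limit gamma -> 0: numerator ~ gamma (1 - x)
    if gamma > 0:
        return np.expm1(-gamma * (1.0 - x)) / np.expm1(-gamma)
    return (np.exp(gamma) - np.exp(gamma * x)) / np.expm1(gamma)


def sfs_integrand(gamma: float, x, i: int, n: int):
    """tau(gamma, x, i): frequency-density integrand of the expected SFS.

    Parameters are the scaled coefficient ``gamma``, population frequency
    ``x`` in (0, 1) (scalar or array), sample frequency class ``i`` and
    sample size ``n``.  At ``gamma == 0`` the limit ``C(n,i) x^{i-1}
    (1-x)^{n-i-1}`` is used.
    """
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if not 1 <= i <= n - 1:
        raise ValueError(f"i must lie in 1..n-1, got i={i}, n={n}")
    xarr = np.asarray(x, dtype=float)
    if np.any(xarr <= 0.0) or np.any(xarr >= 1.0):
        raise ValueError("x must lie strictly in (0, 1)")
    val = (
        _tau_ratio(gamma, xarr)
        / (xarr * (1.0 - xarr))
        * stats.binom.pmf(i, n, xarr)
    )
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(val)
    return val


def _x_rule(m: int):
    x, w = np.polynomial.legendre.leggauss(m)
    return 0.5 * (x + 1.0), 0.5 * w


_PSI_KERNEL_CACHE: dict = {}


def _psi_kernel(n: int, m: int):
    """(x nodes, weights, binomial kernel rows i=1..n-1), cached per (n, m)."""
    if (n, m) not in _PSI_KERNEL_CACHE:
        x, w = _x_rule(m)
        pmf = np.array([stats.binom.pmf(i, n, x) for i in range(1, n)])
        _PSI_KERNEL_CACHE[(n, m)] = (x, w, pmf)
    return _PSI_KERNEL_CACHE[(n, m)]


def _psi_point(gamma: float, n: int, m: int) -> np.ndarray:
    """Vector of integrals over x of tau(gamma, x, i) for i = 1..n-1."""
    x, w, pmf = _psi_kernel(n, m)
    dens = w * _tau_ratio(gamma, x) / (x * (1.0 - x))
    return pmf @ dens


def _psi_dfe(
    dfe: DFEModel, shift: float, n: int, cfg: QuadratureConfig
) -> np.ndarray:
    """DFE-averaged SFS shape including the beneficial point mass."""
    gammas, weights = dfe.deleterious_quadrature(cfg.gamma_nodes)
    out = np.zeros(n - 1)
    for g, w in zip(gammas, weights):
        out += w * _psi_point(g + shift, n, cfg.x_nodes)
    out *= 1.0 - dfe.beneficial_fraction
    if dfe.beneficial_fraction > 0:
        out += dfe.beneficial_fraction * _psi_point(
            dfe.beneficial_gamma + shift, n, cfg.x_nodes
        )
    return out


def expected_class_sfs(
    dfe: DFEModel,
    ctx: GBGCContext,
    cls: MutationClass,
    quad: QuadratureConfig = _DEFAULT_QUAD,
) -> ClassSFS:
    """Expected unfolded SFS (per site) for one mutation class.

    Entry ``i`` equals ``weight_cls * integral of tau(gamma + shift_cls, x, i)``
    over the DFE and over ``x``, with class weight theta / (1-p) theta /
    p kappa theta and shift 0 / +B / -B for WWSS / W->S / S->W.

    With ``quad.check_convergence`` the computation is repeated on doubled
    grids; a relative change above ``quad.tol`` raises
    :class:`QuadratureError`.
    """
    if cls not in _SELECTED_CLASSES:
        raise ValueError(f"expected_class_sfs needs WWSS, WS or SW, got {cls}")
    n = ctx.sample_size
    shift = ctx.class_shift(cls)
    weight = ctx.class_weight(cls)
    entries = weight * _psi_dfe(dfe, shift, n, quad)
    if quad.check_convergence:
        fine = QuadratureConfig(
            x_nodes=2 * quad.x_nodes,
            gamma_nodes=2 * quad.gamma_nodes,
            tol=quad.tol,
        )
        entries_fine = weight * _psi_dfe(dfe, shift, n, fine)
        rel = np.max(
            np.abs(entries - entries_fine) / np.maximum(np.abs(entries_fine), 1e-300)
        )
        if rel > quad.tol:
            raise QuadratureError(
                f"SFS quadrature not converged for {cls}: relative change "
                f"{rel:.2e} after grid doubling (x_nodes={quad.x_nodes}, "
                f"gamma_nodes={quad.gamma_nodes}, tol={quad.tol})"
            )
        entries = entries_fine
    return ClassSFS(cls=cls, entries=entries, sample_size=n, folded=False)


def combined_sfs(
    dfe: DFEModel,
    ctx: GBGCContext,
    quad: QuadratureConfig = _DEFAULT_QUAD,
) -> ClassSFS:
    """Elementwise sum of the three class SFSs ("ignoring gBGC" spectrum)."""
    parts = [expected_class_sfs(dfe, ctx, c, quad) for c in _SELECTED_CLASSES]
    entries = parts[0].entries + parts[1].entries + parts[2].entries
    return ClassSFS(
        cls=MutationClass.COMBINED,
        entries=entries,
        sample_size=ctx.sample_size,
        folded=False,
    )


def fold_sfs(sfs: ClassSFS) -> ClassSFS:
    """Fold an unfolded SFS onto minor-allele frequency classes.

    ``folded[i] = entries[i] + entries[n-i]`` for ``i < n/2``; for even
    ``n`` the midpoint class ``i = n/2`` is unpaired and copied as is.
    """
    if sfs.folded:
        raise ValueError("SFS is already folded")
    n = sfs.sample_size
    half = n // 2
    v = sfs.entries
    out = np.empty(half)
    for i in range(1, half + 1):
        out[i - 1] = v[i - 1] + (v[n - i - 1] if i != n - i else 0.0)
    return ClassSFS(
        cls=sfs.cls,
        entries=out,
        sample_size=n,
        folded=True,
        site_count=sfs.site_count,
    )


def _class_rate(dfe: DFEModel, shift: float, n_nodes: int) -> float:
    """Per-unit-weight substitution rate E_f[u(gamma + shift)] incl. beneficial mass."""
    gammas, weights = dfe.deleterious_quadrature(n_nodes)
    rate = (1.0 - dfe.beneficial_fraction) * float(
        np.sum(weights * fixation_rate_ratio(gammas + shift))
    )
    if dfe.beneficial_fraction > 0:
        rate += dfe.beneficial_fraction * fixation_rate_ratio(
            dfe.beneficial_gamma + shift
        )
    return rate


def expected_divergence(
    dfe: DFEModel,
    ctx: GBGCContext,
    t_theta: float,
    quad: QuadratureConfig = _DEFAULT_QUAD,
) -> DivergenceSummary:
    """Expected per-class divergence over a branch of length ``t_theta = T*theta``.

    ``k_wwss = T theta E_f[u(gamma)]``, ``k_ws = T (1-p) theta
    E_f[u(gamma+B)]``, ``k_sw = T p kappa theta E_f[u(gamma-B)]``.
    """
    if t_theta <= 0:
        raise ValueError("t_theta must be > 0")
    p = ctx.gc_content
    k = {}
    for cls, rel_weight in (
        (MutationClass.WWSS, 1.0),
        (MutationClass.WS, 1.0 - p),
        (MutationClass.SW, p * ctx.kappa),
    ):
        rate = _class_rate(dfe, ctx.class_shift(cls), quad.gamma_nodes)
        if quad.check_convergence:
            rate_fine = _class_rate(dfe, ctx.class_shift(cls), 2 * quad.gamma_nodes)
            if abs(rate - rate_fine) > quad.tol * max(abs(rate_fine), 1e-300):
                raise QuadratureError(
                    f"divergence quadrature not converged for {cls} "
                    f"(gamma_nodes={quad.gamma_nodes})"
                )
            rate = rate_fine
        k[cls] = t_theta * rel_weight * rate
    return DivergenceSummary(
        k_wwss=k[MutationClass.WWSS],
        k_ws=k[MutationClass.WS],
        k_sw=k[MutationClass.SW],
        t_theta=t_theta,
    )


def _restricted_classes(ctx: GBGCContext, restrict: str):
    """(relative weight, shift) pairs for the requested class restriction."""
    restrict = restrict.upper()
    if restrict == "WWSS":
        return [(1.0, 0.0)]
    if restrict == "ALL":
        p = ctx.gc_content
        return [(1.0, 0.0), (1.0 - p, ctx.B), (p * ctx.kappa, -ctx.B)]
    raise ValueError(f"restrict must be 'ALL' or 'WWSS', got {restrict!r}")


def true_alpha(
    dfe: DFEModel,
    ctx: GBGCContext,
    restrict: str = "ALL",
    n_nodes: int = 256,
) -> float:
    """Analytic proportion of substitutions driven by positive selection.

    The beneficial substitution rate (contributions with gamma > 0, i.e. the
    beneficial point mass, summed over the requested classes with their gBGC
    shifts) divided by the total substitution rate over the same classes.
    The WWSS restriction is invariant in B.
    """
    classes = _restricted_classes(ctx, restrict)
    x = dfe.beneficial_fraction
    beneficial = sum(
        w * x * fixation_rate_ratio(dfe.beneficial_gamma + s) for w, s in classes
    )
    gammas, weights = dfe.deleterious_quadrature(n_nodes)
    deleterious = sum(
        w * (1.0 - x) * float(np.sum(weights * fixation_rate_ratio(gammas + s)))
        for w, s in classes
    )
    total = beneficial + deleterious
    if total <= 0:
        raise ZeroDivisionError("total substitution rate is zero; alpha undefined")
    return beneficial / total


def true_omega_a(
    dfe: DFEModel,
    ctx: GBGCContext,
    restrict: str = "ALL",
    n_nodes: int = 256,
) -> float:
    """Analytic rate of adaptive substitution relative to neutral divergence.

    The beneficial substitution rate over the requested classes divided by
    the neutral divergence of the same classes (the same context with a
    neutral DFE).  For WWSS this reduces to the closed form
    ``beneficial_fraction * u(beneficial_gamma)``.
    """
    classes = _restricted_classes(ctx, restrict)
    x = dfe.beneficial_fraction
    beneficial = sum(
        w * x * fixation_rate_ratio(dfe.beneficial_gamma + s) for w, s in classes
    )
    neutral = sum(w * fixation_rate_ratio(s) for w, s in classes)
    if neutral <= 0:
        raise ZeroDivisionError("neutral divergence is zero; omega_a undefined")
    return beneficial / neutral
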