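"""Maximum-likelihood DFE inference from folded spectra.

The estimation procedure follows the classical two-step design: first a
two-epoch demographic model (single step change in population size) is
fitted to the folded SFS of a neutral reference class; then, conditional on
the fitted demography, a deleterious gamma DFE is fitted to the folded SFS
of the selected class.  Together with observed (or model) divergence at
selected and neutral sites the fitted DFE yields the proportion of
substitutions fixed by positive selection,

    alpha = 1 - (K4 / K0) * E_fd[u(gamma)],

and the relative rate of adaptive substitution,

    omega_a = K0 / K4 - E_fd[u(gamma)],

where ``u`` is the fixation-rate ratio and ``f_d`` the fitted deleterious
DFE.

Likelihoods are independent Poisson counts per folded frequency class with
the overall scale profiled out analytically (the monomorphic class is
absorbed into this nuisance scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .models import ClassSFS, DFEModel, NesBinProportions, TwoEpochDemography
from .prf import fixation_rate_ratio
from .wright_fisher import WrightFisherEngine

__all__ = [
    "DemographyFit",
    "GammaDFEFit",
    "OptimizationError",
    "fit_two_epoch",
    "fit_gamma_dfe",
    "alpha_from_dfe",
    "omega_a_from_dfe",
    "dfe_mass_in_bins",
    "bootstrap_by_gene",
]

logger = logging.getLogger(__name__)


class OptimizationError(RuntimeError):
    pass


def _poisson_nll(obs: np.ndarray, expected: np.ndarray) -> float:
    """Poisson NLL over frequency classes with the scale profiled out."""
    total = expected.sum()
    if total <= 0 or not np.all(np.isfinite(expected)):
        return np.inf
    lam = (obs.sum() / total) * expected
    lam = np.maximum(lam, 1e-300)
    return float(-np.sum(obs * np.log(lam) - lam))


@dataclass(frozen=True)
class DemographyFit:
    demography: TwoEpochDemography
    log_likelihood: float
    #: discretized second-epoch size (diploids) and age (generations) at the
    #: engine's base level, for exact reuse by the conditional DFE fit
    n2: int = 0
    gens: int = 0
    #: callable sites behind the neutral SFS; with ``ancestral_scale`` this
    #: pins the per-site mutation scale that the selected-class fit inherits
    site_count: float = 1.0


@dataclass(frozen=True)
class GammaDFEFit:
    dfe: DFEModel
    log_likelihood: float
    scale: float = 1.0


def _profile_change_time(
    engine: WrightFisherEngine, obs: np.ndarray, n2: int, max_time: float
) -> Tuple[float, int]:
    """Best (nll, generations) for a fixed second-epoch size.

    The whole trajectory is scored generation by generation; iteration stops
    early once the likelihood has not improved for half an epoch-2
    population turnover (the spectrum is then effectively equilibrated at
    the new size and the profile is flat).
    """
    if n2 == engine.n_ref:
        # same size in both epochs: every change time gives the same SFS
        return _poisson_nll(obs, engine.folded_sfs(0.0)), 0
    max_gens = int(round(max_time * 2 * n2))
    patience = max(50, n2)
    best = (np.inf, 0)
    for gens, sfs in engine.neutral_trajectory(n2, max_gens):
        nll = _poisson_nll(obs, sfs)
        if nll < best[0]:
            best = (nll, gens)
        elif gens - best[1] > patience:
            break
    return best


def fit_two_epoch(
    neutral_sfs: ClassSFS,
    engine: Optional[WrightFisherEngine] = None,
    size_ratio_range: Tuple[float, float] = (0.25, 4.0),
    max_change_time: float = 2.5,
    n_coarse: int = 13,
    coarse_n_ref: int = 100,
) -> DemographyFit:
    """ML two-epoch demography for a folded neutral SFS.

    The search space is discrete: the second-epoch size ``N2`` runs over
    integer diploid counts and the age of the size change over integer
    generation counts, which lets the time dimension be profiled exactly in
    one forward pass per candidate size (every generation along the
    trajectory is scored).  A coarse scan over log-spaced size ratios on a
    smaller reference population locates the optimum; the final engine then
    refines the size locally.  This plays the role of the usual multi-start
    strategy while being deterministic.
    """
    if not neutral_sfs.folded:
        raise ValueError("fit_two_epoch expects a folded SFS")
    if neutral_sfs.n_segregating <= 0:
        raise OptimizationError("neutral SFS has no segregating sites")
    if engine is None:
        engine = WrightFisherEngine(sample_size=neutral_sfs.sample_size)
    if engine.sample_size != neutral_sfs.sample_size:
        raise ValueError("engine sample_size does not match the SFS")
    obs = neutral_sfs.entries

    coarse = WrightFisherEngine(
        n_ref=coarse_n_ref,
        sample_size=engine.sample_size,
        extrapolate=engine.extrapolate,
    )
    lo, hi = size_ratio_range
    ratios = np.geomspace(lo, hi, n_coarse)
    results = {}
    for r in ratios:
        n2 = max(5, int(round(r * coarse.n_ref)))
        if n2 not in results:
            results[n2] = _profile_change_time(coarse, obs, n2, max_change_time)
    best_n2 = min(results, key=lambda k: results[k][0])
    # local integer refinement at coarse resolution
    span = max(2, int(round(0.08 * best_n2)))
    for n2 in range(best_n2 - span, best_n2 + span + 1):
        if n2 >= 5 and n2 not in results:
            results[n2] = _profile_change_time(coarse, obs, n2, max_change_time)
    best_n2 = min(results, key=lambda k: results[k][0])
    r_star = best_n2 / coarse.n_ref

    # refinement on the final engine around the coarse optimum
    step = max(1, engine.n_ref // 200)
    center = int(round(r_star * engine.n_ref))
    fine: dict = {}
    for n2 in range(center - 3 * step, center + 3 * step + 1, step):
        if n2 >= 5:
            fine[n2] = _profile_change_time(engine, obs, n2, max_change_time)
    if not fine:
        raise OptimizationError("two-epoch size search produced no candidates")
    best_n2 = min(fine, key=lambda k: fine[k][0])
    nll, gens = fine[best_n2]
    if not np.isfinite(nll):
        raise OptimizationError("two-epoch likelihood not finite at the optimum")

    expected = engine.folded_sfs(0.0, best_n2, gens)
    scale = obs.sum() / expected.sum()
    demog = TwoEpochDemography(
        size_ratio=best_n2 / engine.n_ref,
        change_time=gens / (2.0 * best_n2),
        ancestral_scale=float(scale),
    )
    return DemographyFit(
        demography=demog,
        log_likelihood=-nll,
        n2=best_n2,
        gens=gens,
        site_count=neutral_sfs.site_count,
    )


# DFE integration grid on |gamma|: geometric bins spanning effectively
# neutral (1e-4) to far beyond lethal-equivalent (1e6); mass below/above is
# lumped into the first/last node.
_GAMMA_EDGES = np.concatenate(([0.0], np.geomspace(1e-4, 1e6, 121), [np.inf]))
_GAMMA_MIDS = np.concatenate(
    ([0.0], np.sqrt(_GAMMA_EDGES[1:-2] * _GAMMA_EDGES[2:-1]), [_GAMMA_EDGES[-2]])
)

_DFE_STARTS = [
    (b0, m0) for b0 in (0.1, 0.2, 0.4, 0.8) for m0 in (10.0, 1e2, 1e3, 1e4)
]


def fit_gamma_dfe(
    selected_sfs: ClassSFS,
    demog_fit: DemographyFit,
    engine: Optional[WrightFisherEngine] = None,
    starts: Sequence[Tuple[float, float]] = tuple(_DFE_STARTS),
) -> GammaDFEFit:
    """ML gamma DFE (deleterious-only) for a folded selected SFS.

    The expected SFS under a candidate ``(beta, mean_gamma)`` is a mixture of
    point-coefficient spectra precomputed on a fixed geometric ``|gamma|``
    grid under the fitted demography, weighted by the gamma-distribution
    mass in each grid bin.  Optimization is a derivative-free simplex on
    ``(log beta, log |mean_gamma|)`` from the multi-start grid.

    The per-site mutation scale is inherited from the neutral fit (scaled by
    the ratio of callable site counts), not refitted: the deficit of
    selected polymorphism relative to the neutral expectation is exactly
    what identifies the strongly deleterious DFE mass that never
    segregates.  A free scale would make arbitrarily lethal mass costless.
    """
    if not selected_sfs.folded:
        raise ValueError("fit_gamma_dfe expects a folded SFS")
    if engine is None:
        engine = WrightFisherEngine(sample_size=selected_sfs.sample_size)
    obs = selected_sfs.entries
    n2, gens = demog_fit.n2, demog_fit.gens
    if n2 <= 0:
        n2, gens = engine.discretize(demog_fit.demography)
    grid = np.array([engine.folded_sfs(-m, n2, gens) for m in _GAMMA_MIDS])
    tied_scale = demog_fit.demography.ancestral_scale * (
        selected_sfs.site_count / demog_fit.site_count
    )

    def nll(v: np.ndarray) -> float:
        beta, mabs = np.exp(v)
        if not (0.01 < beta < 5.0 and 1e-3 < mabs < 1e7):
            return 1e12
        wts = np.diff(stats.gamma.cdf(_GAMMA_EDGES, a=beta, scale=mabs / beta))
        lam = np.maximum(tied_scale * (wts @ grid), 1e-300)
        return float(-np.sum(obs * np.log(lam) - lam))

    best = None
    for b0, m0 in starts:
        res = optimize.minimize(
            nll,
            [np.log(b0), np.log(m0)],
            method="Nelder-Mead",
            options=dict(xatol=1e-6, fatol=1e-8, maxiter=800),
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise OptimizationError("all gamma-DFE starts failed to converge")
    beta, mabs = np.exp(best.x)
    dfe = DFEModel(shape_beta=float(beta), mean_gamma=float(-mabs))
    return GammaDFEFit(
        dfe=dfe, log_likelihood=-float(best.fun), scale=float(tied_scale)
    )


def _mean_fixation_ratio(dfe: DFEModel, n_nodes: int = 256) -> float:
    gammas, weights = dfe.deleterious_quadrature(n_nodes)
    return float(np.sum(weights * fixation_rate_ratio(gammas)))


def alpha_from_dfe(dfe: DFEModel, k0: float, k4: float) -> float:
    """Proportion of adaptive substitutions from a fitted deleterious DFE.

    ``alpha = 1 - (k4/k0) E_fd[u(gamma)]`` with ``k0``/``k4`` the divergence
    at selected/neutral sites.
    """
    if k4 <= 0:
        raise ValueError("k4 must be > 0")
    if k0 == 0:
        raise ZeroDivisionError("k0 is zero; alpha undefined")
    return 1.0 - (k4 / k0) * _mean_fixation_ratio(dfe)


def omega_a_from_dfe(dfe: DFEModel, k0: float, k4: float) -> float:
    """Adaptive substitution rate relative to neutral divergence (``k0/k4 - E_fd[u]``)."""
    if k4 <= 0:
        raise ValueError("k4 must be > 0")
    return k0 / k4 - _mean_fixation_ratio(dfe)


def dfe_mass_in_bins(
    dfe: DFEModel,
    edges: Tuple[float, float] = (1.0, 10.0),
    nes_scale: float = 4.0,
) -> NesBinProportions:
    """Proportions of new deleterious mutations by N_e*s bin.

    ``edges`` are on the N_e*s scale; the model works with ``gamma = 4 N s``,
    so edges are multiplied by ``nes_scale`` (default 4) before evaluating
    the gamma CDF.  Pass ``nes_scale=1`` to interpret the edges directly on
    the gamma scale.
    """
    e1, e2 = (nes_scale * e for e in edges)
    if dfe.mean_gamma == 0.0:
        return NesBinProportions(1.0, 0.0, 0.0)
    cdf = stats.gamma.cdf(
        [e1, e2], a=dfe.shape_beta, scale=dfe.gamma_scale
    )
    return NesBinProportions(
        nearly_neutral=float(cdf[0]),
        intermediate=float(cdf[1] - cdf[0]),
        strong=float(1.0 - cdf[1]),
    )


def bootstrap_by_gene(
    genes: Sequence,
    statistic: Callable[[Sequence], float],
    reps: int = 100,
    seed: int = 0,
    percentiles: Tuple[float, float] = (2.5, 97.5),
) -> Tuple[float, float]:
    """Percentile bootstrap CI of ``statistic`` over gene resamples.

    Genes are resampled with replacement; replicates for which the statistic
    is undefined (raises or returns NaN, e.g. a degenerate resample with no
    sites) are skipped and counted in the log.
    """
    if len(genes) < 2:
        raise ValueError("bootstrap needs at least 2 genes")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    values = []
    skipped = 0
    for _ in range(reps):
        idx = rng.integers(0, len(genes), size=len(genes))
        try:
            v = statistic([genes[i] for i in idx])
        except (ZeroDivisionError, ValueError, FloatingPointError):
            skipped += 1
            continue
        if v is None or not np.isfinite(v):
            skipped += 1
            continue
        values.append(v)
    if skipped:
        logger.info("bootstrap_by_gene: skipped %d degenerate replicates", skipped)
    if not values:
        raise OptimizationError("all bootstrap replicates were degenerate")
    lo, hi = np.percentile(values, percentiles)
    return float(lo), float(hi)
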