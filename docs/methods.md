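# Methods

## The model

The package treats every site as an independent realization of a
Wright–Fisher diffusion (a Poisson random field): linkage, interference and
hitch-hiking are outside the model.  A new mutation has a scaled selection
coefficient γ = 4Ns (s the heterozygote fitness difference, positive =
beneficial), and GC-biased gene conversion (gBGC) acts like additive
selection of strength B = 4Nb on any A/T↔G/C ("weak/strong") heterozygote.
Mutations therefore fall into three classes:

| class | mutational input | effective coefficient |
|-------|------------------|-----------------------|
| WWSS (A↔T, C↔G) | θ | γ |
| W→S (A/T → G/C) | (1−p) θ | γ + B |
| S→W (G/C → A/T) | p κ θ | γ − B |

with p the (time-constant) GC content, κ the GC→AT mutational bias and
θ = 4Nu per site.  The expected unfolded sample SFS of a class is

ψ(i) = w · ∫∫ τ(γ + shift, x, i) f(γ) dx dγ,
τ(γ,x,i) = [1 − e^{−γ(1−x)}] / [(1 − e^{−γ}) x (1−x)] · C(n,i) x^i (1−x)^{n−i},

and the expected divergence over a branch of length T (units of 4N
generations) uses the fixation-rate ratio u(γ) = γ / (1 − e^{−γ}):
K_class = T w E_f[u(γ + shift)].  The DFE f is a reflected gamma
(−γ ~ Gamma(β, mean −γ̄)) plus an optional beneficial point mass (fraction
x at coefficient γ_b).  From these rates the analytic ("true") proportion
of adaptive substitutions is the beneficial share of the total substitution
rate, and the true ω_a divides the beneficial rate by the neutral
divergence of the same classes; both can be restricted to the WWSS class,
in which case they are exactly invariant in B.

Estimated α and ω_a follow the classical polymorphism/divergence recipe:
α = 1 − (K₄/K₀) E_fd[u(γ)] and ω_a = K₀/K₄ − E_fd[u(γ)], with f_d a
deleterious gamma DFE fitted to the selected-class SFS.

## Numerics of the expectations

* τ and u are evaluated in rewritten forms so that only exponentials of
  negative arguments occur; |γ| up to 10⁴ and beyond is safe, and the γ→0
  limits (τ numerator → γ(1−x), u → 1) are taken explicitly.
* The x-integral is a 256-node Gauss–Legendre rule on (0,1); for sample
  sizes up to a few hundred the integrand is polynomial-like and the rule
  is exact to machine precision.
* The γ-integral uses composite Gauss–Legendre on log |γ| between 10⁻⁸ and
  the 1−10⁻¹⁴ gamma quantile (16-node panels, 256 nodes total), with the
  probability mass below 10⁻⁸ carried by an explicit node at γ = 0.
  Doubling the node count moves the expected spectra by ≲10⁻¹⁰ relative.
  A global rule on equiprobable mass was tried first and converged far too
  slowly (≈5·10⁻⁵ at 256→512 nodes) because the integrand spans many
  decades of γ; the log-axis composite rule is the design consequence.
* `QuadratureConfig(check_convergence=True)` re-evaluates on doubled grids
  and raises if the result moves by more than `tol`.

## The Wright–Fisher engine

DFE inference needs expected spectra under a two-epoch demography, which
has no closed form.  The engine iterates a discrete Wright–Fisher
population: selection through the haploid-equivalent update
q' = q(1+s)/(1+qs) with s = γ/(4N_ref) (clamped at s ≥ −0.999; more
negative coefficients are effectively lethal and contribute no
polymorphism), drift through banded binomial transition matrices (8 σ
bands; truncated mass < 10⁻¹⁴), one new mutation per generation at count 1
(scaled by N₂/N₁ in the second epoch), and binomial sampling of n
chromosomes.

A plain matrix at any affordable reference size is visibly biased relative
to the diffusion (≈8% shape error at N = 100, falling like 1/N), and a
5·10⁶-site likelihood amplifies that bias into large parameter distortions.
The engine therefore evaluates every quantity at reference sizes N and 2N
(generations and epoch sizes doubled in step) and Richardson-extrapolates,
2·v(2N) − v(N), which cancels the leading 1/N term.  With the default
N_ref = 200 the constant-size selected spectrum at γ = −10 agrees with the
independent quadrature to ≈5·10⁻⁴ relative, and the full pipeline run on
noise-free B = 0 data returns the generating DFE to ≈1% (β) / ≈2% (γ̄) —
the self-consistency check that justifies using the same engine inside the
bias study.

## Fitting

Both fits use independent Poisson counts per folded minor-allele class.

*Demography.*  The two-epoch model (size ratio N₂/N₁, change age t₂ in
units of 2N₂ generations) is discrete in the engine: N₂ is an integer
diploid count and t₂ an integer generation count.  The fit exploits this:
for each candidate N₂ a single forward pass scores every generation along
the trajectory (profiling t₂ exactly, with early stopping once the
likelihood has been flat for a population turnover), over a log-spaced
coarse grid of size ratios (0.25–4, 13 candidates, evaluated on a cheaper
N_ref = 100 engine) followed by integer refinement on the full engine.
This replaces the usual multi-start simplex with a deterministic exhaustive
profile.  The change-age search extends to 2.5 (units of 2N₂ generations;
≈5 N₂ generations), beyond which the spectrum is equilibrated at the new
size and the profile is flat.  The overall scale (θ per site × sites) is
profiled analytically; the monomorphic class is absorbed into it.

*DFE.*  Conditional on the fitted demography, point-coefficient spectra are
precomputed on a fixed geometric grid of 121 |γ| values (10⁻⁴–10⁶, plus a
neutral node and an overflow bin), and a candidate (β, γ̄) predicts the SFS
as the gamma-mass-weighted mixture.  Optimization is Nelder–Mead on
(log β, log|γ̄|) from a 4×4 multi-start grid (β ∈ {0.1, 0.2, 0.4, 0.8},
γ̄ ∈ {−10, −10², −10³, −10⁴}).  The mutation scale is **not** refitted: it
is inherited from the neutral fit, rescaled by the ratio of callable site
counts.  This is essential, not cosmetic — the strongly deleterious DFE
mass is identified precisely by the deficit of selected polymorphism
relative to the neutral expectation, and with a free scale the likelihood
becomes asymptotically flat in |γ̄| (arbitrarily lethal mass costs
nothing), sending the optimizer to the search boundary.

*N_e·s bins.*  Reported bin proportions (< 1, 1–10, > 10) evaluate the
gamma CDF after mapping the edges to the γ = 4Ns scale (factor 4 by
default, switchable to 1; the right convention is genuinely ambiguous and
neither is asserted in acceptance checks).

*Bootstrap.*  Gene-level resampling with replacement, percentile 95% CIs,
seeded; degenerate replicates (undefined statistic) are skipped and
counted.

## The ignoring-gBGC bias study

For each parameter case and each B the study (i) builds the expected —
noise-free — combined (WWSS + W→S + S→W) neutral and selected spectra,
scaled to 5·10⁶ sites each; (ii) removes the beneficial fraction x from the
selected spectrum while keeping the full site count, so the fit sees a
(small) polymorphism deficit and absorbs it as extra strongly deleterious
mass — which is exactly right, because the α estimator assumes every
selected site feeds deleterious mutations, and E_fd[u] must come out as
(1−x)·E[u] for α̂ to equal the true α when nothing else is misspecified
(verified analytically and by the B = 0 rows); (iii) fits demography and
deleterious gamma DFE
with the machinery above, blind to gBGC; (iv) computes K₀ and K₄ from the
*true* parameters (Tθ = 1; it cancels in the ratio) and evaluates α̂ and
ω̂_a with the *fitted* DFE; (v) tabulates everything against the analytic
true values.  Expected spectra rather than sampled ones are used on
purpose: the object of study is the expected bias, not sampling noise.

The qualitative outcome is robust: at B = 0 the pipeline is honest
(case 1 α̂ < 0.001), and as B grows the fitted β shrinks, |γ̄| inflates and
α̂/ω̂_a are overestimated relative to their true values, increasingly so
with B.  Quantitatively, the fitted columns at B > 0 sit on an almost flat
(β, γ̄) likelihood ridge created by model misspecification (the gBGC-shifted
classes cannot be represented by any deleterious gamma), so their exact
values are sensitive to engine details; comparisons against externally
published fits should expect agreement in β̂ (observed ≲2.5%) but only
order-of-magnitude-level agreement in ridge-dominated quantities.

## Synthetic data

The generator emulates the structure of a two-species resequencing study:
per-species folded 0-fold/4-fold spectra under two-epoch growth, a gamma
DFE with a beneficial point mass, gBGC class structure (so WWSS vs
GC-changing variants can be split), Poisson-sampled per-gene divergence
counts from the model's expected rates, a toy one-chromosome genome with
one CDS per gene and a GC₄ gradient, and a smooth genetic map.  The default
pair contrasts a small-N_e and a large-N_e species with a 2.83-fold θ
ratio (0.0035 vs 0.0099), the same underlying fitness-effect distribution
(so scaled parameters γ̄, γ_b, B are 2.83× stronger in the large-N_e
species), shared demography (doubling 0.25·2N₂ generations ago), p = 0.472,
κ = 2, and n = 20 chromosomes.  Variants are independent Poisson draws per
frequency class assigned to equal-sized genes; there is no linkage, no
codon-realistic placement of degenerate sites (a small codon-true FASTA is
generated for degeneracy code paths), no sequencing error and no missing
genotypes.  Passing tests on these data demonstrate internal consistency
of the estimators under the model's own assumptions, not robustness to the
artifacts of real resequencing data.

Default problem sizes (5·10⁶ sites for the theoretical study, 10⁶ for the
acceptance-script species pair, 2–3·10⁵ for the test fixtures) were chosen
so expected counts dominate sampling noise in the quantities each check
asserts; the per-gene split (200–300 genes) only matters for bootstrap and
binning code paths.

## Degenerate inputs and edge rules

* Folded spectra of odd n have no unpaired midpoint; even n keeps the n/2
  class unpaired.  Folding a folded SFS raises.
* Tajima's D is reported as undefined (None/NaN) when S = 0; π and θ_W are
  0 then.
* Stop codons are excluded from degeneracy classes (`stop_adjacent`);
  substitutions creating a stop count as amino-acid-changing.
* Negative derivatives of the cubic map polynomial are clamped to 0 (map
  length cannot decrease) with a warning; M/C windows clip to the marker
  range and flag C = 0 as NaN.
* Tertile bins use `np.array_split` semantics (sizes ±1, larger bins
  first) with ties broken by gene identifier for determinism.

## Known limitations

* Independent-sites assumption throughout; no linked selection, no
  recombination within the simulated data.
* The gBGC model is additive in γ and assumes constant GC content and no
  transition/transversion structure beyond κ.
* Polymorphism analysis is folded/unpolarized: W→S cannot be separated
  from S→W, so empirical gBGC control is restricted to the WWSS subset.
* The demographic model is a single step change; richer histories will be
  absorbed imperfectly and leak into the DFE, exactly as the bias study
  quantifies for gBGC.
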