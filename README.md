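# gbgcdfe

Inference of the distribution of fitness effects (DFE) and of the
prevalence of adaptive substitution — α, the proportion of between-species
substitutions fixed by positive selection, and ω_a, the adaptive
substitution rate relative to neutral divergence — with explicit treatment
of GC-biased gene conversion (gBGC).

gBGC is a neutral, recombination-associated process that transmits G/C
alleles preferentially from A/T-G/C heterozygotes.  It behaves like
selection of strength B = 4Nb on every "weak"(A/T)↔"strong"(G/C) variant,
distorting both the site-frequency spectrum (SFS) and divergence.  Analyses
that estimate the DFE from polymorphism and then ask whether divergence
exceeds the deleterious expectation (the DFE-α family of methods) can
mistake that distortion for positive selection.  This package provides

* a Poisson-random-field model of the expected SFS and divergence for the
  three mutation classes — GC-conservative (WWSS: A↔T, C↔G), W→S and S→W —
  under an arbitrary gamma + beneficial-point-mass DFE and gBGC strength B,
  with analytic "true" α and ω_a;
* a DFE-inference engine: two-epoch demographic fit on a folded neutral
  SFS, deleterious gamma-DFE fit on the selected SFS (a Wright–Fisher
  transition-matrix engine with Richardson extrapolation to the diffusion
  limit), then α̂ = 1 − (K₄/K₀)·E[u(γ)] and ω̂_a = K₀/K₄ − E[u(γ)];
* the full "ignoring gBGC" bias experiment: generate expected spectra with
  gBGC, fit them while ignoring it, and tabulate the inflation of α̂ and
  ω̂_a against the analytic truth across B ∈ {0, 1, 3, 5, 10};
* empirical building blocks: WWSS classification of SNPs, folded SFS
  construction from allele counts or VCF, π / Watterson's θ / Tajima's D,
  codon degeneracy (0-fold/4-fold), GC₄, cubic genetic-map smoothing with
  derivative recombination rates, ±500 kb map-length-per-coding-site (M/C)
  windows, equal-sized tertile gene bins, and gene-level bootstrap CIs;
* a synthetic-data generator producing a complete two-species toy study
  (allele counts, divergence, annotation, genome, genetic maps) with a
  configurable N_e contrast, so the entire pipeline runs with no external
  data.

## Worked example

Case: strong gBGC (B = 5), a leptokurtic deleterious DFE
(β = 0.2, mean γ = −40) and 3% beneficial mutations with γ_b = 10, at
5·10⁶ selected and neutral sites — then analysed while ignoring gBGC:

```python
import numpy as np
from gbgcdfe import (
    DFEModel, GBGCContext, combined_sfs, fold_sfs, expected_divergence,
    true_alpha, fit_two_epoch, fit_gamma_dfe, alpha_from_dfe,
    omega_a_from_dfe, dfe_mass_in_bins, WrightFisherEngine,
)
from gbgcdfe.models import ClassSFS

ctx = GBGCContext(B=5.0, kappa=2.0, gc_content=0.472, theta=0.01, sample_size=50)
dfe = DFEModel(shape_beta=0.2, mean_gamma=-40.0,
               beneficial_fraction=0.03, beneficial_gamma=10.0)
neutral_dfe = DFEModel(shape_beta=1.0, mean_gamma=0.0)

n_sites = 5e6
neutral = fold_sfs(combined_sfs(neutral_dfe, ctx)).scaled(n_sites)
deleterious = DFEModel(shape_beta=0.2, mean_gamma=-40.0)
sel = fold_sfs(combined_sfs(deleterious, ctx))
selected = ClassSFS(cls=sel.cls, entries=sel.entries * 0.97 * n_sites,
                    sample_size=50, folded=True, site_count=n_sites)

engine = WrightFisherEngine(sample_size=50)
demog = fit_two_epoch(neutral, engine=engine)
fit = fit_gamma_dfe(selected, demog, engine=engine)
k0 = expected_divergence(dfe, ctx, 1.0).k_total
k4 = expected_divergence(neutral_dfe, ctx, 1.0).k_total
print(f"true alpha (all sites)   : {true_alpha(dfe, ctx, 'ALL'):.4f}")
print(f"true alpha (WWSS only)   : {true_alpha(dfe, ctx, 'WWSS'):.4f}")
print(f"fitted beta              : {fit.dfe.shape_beta:.4f}")
print(f"fitted mean gamma        : {fit.dfe.mean_gamma:.1f}")
print(f"alpha-hat ignoring gBGC  : {alpha_from_dfe(fit.dfe, k0, k4):.4f}")
print(f"omega_a-hat ignoring gBGC: {omega_a_from_dfe(fit.dfe, k0, k4):.4f}")
print(f"P(Ne*s < 1)              : {dfe_mass_in_bins(fit.dfe).nearly_neutral:.3f}")
```

Output:

```
true alpha (all sites)   : 0.3065
true alpha (WWSS only)   : 0.4442
fitted beta              : 0.1719
fitted mean gamma        : -53.9
alpha-hat ignoring gBGC  : 0.3188
omega_a-hat ignoring gBGC: 0.1918
P(Ne*s < 1)              : 0.509
```

Reading it: gBGC of strength 5 depresses the true all-sites α from 0.444
(the WWSS value, which is immune to gBGC) to 0.307, because gBGC both
fixes slightly deleterious W→S mutations and blocks beneficial S→W ones.
The gBGC-blind fit meanwhile distorts the DFE (β̂ = 0.172 instead of 0.2)
so that α̂ = 0.32 stays near the B = 0 truth — i.e. the analysis silently
overestimates adaptation relative to what is really happening at B = 5.  Restricting to WWSS variants, or modelling B explicitly, avoids
the bias.

The same experiment over the full B grid:

```bash
gbgcdfe study --case case3 --out rows.tsv --compare
```

Other entry points: `gbgcdfe fit` (folded SFS files + per-gene divergence
→ JSON with demography, DFE, α, ω_a, N_e·s bins) and `gbgcdfe synth`
(two-species synthetic bundles).

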