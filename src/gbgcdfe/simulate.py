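"""Synthetic data generation.

Produces every input the pipeline consumes without any external download:
Poisson-sampled site-frequency spectra from model expectations, a
two-species toy data bundle (0-fold/4-fold allele counts partitioned into
WWSS and GC-changing variants, per-gene divergence counts, toy annotation,
genome sequence and genetic maps).

Sites are treated as independent (Poisson random field), consistent with
the model the inference assumes; linked selection is deliberately not
simulated.  The default species pair mirrors a small-Ne / large-Ne
contrast with a 2.83-fold difference in neutral diversity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    ClassSFS,
    DFEModel,
    GBGCContext,
    MutationClass,
    TwoEpochDemography,
)
from .prf import expected_divergence
from .wright_fisher import WrightFisherEngine

__all__ = [
    "SyntheticScenario",
    "sample_sfs",
    "expected_scenario_sfs",
    "make_two_species_dataset",
    "default_species_pair",
]

_WWSS_PAIRS = (("A", "T"), ("C", "G"))
_WS_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass(frozen=True)
class SyntheticScenario:
    """Generating model for one species' data set."""

    name: str
    dfe: DFEModel
    ctx: GBGCContext
    demog: TwoEpochDemography
    n_neutral_sites: int = 1_000_000
    n_selected_sites: int = 1_000_000
    n_genes: int = 300
    t_theta: float = 0.02


def sample_sfs(expected: ClassSFS, n_sites: float, seed: int) -> ClassSFS:
    """Poisson-sample an expected SFS scaled to ``n_sites`` sites."""
    if not np.all(np.isfinite(expected.entries)):
        raise ValueError("expected SFS has non-finite entries")
    lam = expected.entries * (n_sites / expected.site_count)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(float)
    return ClassSFS(
        cls=expected.cls,
        entries=counts,
        sample_size=expected.sample_size,
        folded=expected.folded,
        site_count=n_sites,
    )


def _dfe_grid(n_points: int = 61) -> Tuple[np.ndarray, np.ndarray]:
    edges = np.concatenate(([0.0], np.geomspace(1e-4, 1e6, n_points), [np.inf]))
    mids = np.concatenate(
        ([0.0], np.sqrt(edges[1:-2] * edges[2:-1]), [edges[-2]])
    )
    return edges, mids


def expected_scenario_sfs(
    scenario: SyntheticScenario,
    engine: Optional[WrightFisherEngine] = None,
    grid_points: int = 61,
) -> Dict[str, Dict[MutationClass, ClassSFS]]:
    """Per-site folded expected spectra by site class and mutation class.

    Neutral (4-fold) spectra use point coefficients 0 / +B / -B under the
    scenario demography; selected (0-fold) spectra integrate the DFE over a
    geometric grid of coefficients, with the class gBGC shift applied, via
    the Wright-Fisher engine.  The engine's neutral constant-size output is
    normalized so a class of weight w*theta has entries w*theta/i.
    """
    ctx, dfe = scenario.ctx, scenario.dfe
    n = ctx.sample_size
    if engine is None:
        engine = WrightFisherEngine(n_ref=100, sample_size=n)
    n2, gens = engine.discretize(scenario.demog)
    p, B = ctx.gc_content, ctx.B
    classes = (
        (MutationClass.WWSS, 1.0, 0.0),
        (MutationClass.WS, 1.0 - p, B),
        (MutationClass.SW, p * ctx.kappa, -B),
    )
    edges, mids = _dfe_grid(grid_points)
    from scipy import stats

    dfe_wts = np.diff(
        stats.gamma.cdf(edges, a=dfe.shape_beta, scale=dfe.gamma_scale)
    ) if dfe.mean_gamma < 0 else np.concatenate(([1.0], np.zeros(len(mids) - 1)))

    out: Dict[str, Dict[MutationClass, ClassSFS]] = {"fourfold": {}, "zerofold": {}}
    for cls, w, shift in classes:
        neutral = ctx.theta * w * engine.folded_sfs(shift, n2, gens)
        out["fourfold"][cls] = ClassSFS(
            cls=cls, entries=neutral, sample_size=n, folded=True, site_count=1.0
        )
        sel = np.zeros(n // 2)
        for m, wt in zip(mids, dfe_wts):
            if wt > 0:
                sel += wt * engine.folded_sfs(-m + shift, n2, gens)
        sel *= 1.0 - dfe.beneficial_fraction
        if dfe.beneficial_fraction > 0:
            sel += dfe.beneficial_fraction * engine.folded_sfs(
                dfe.beneficial_gamma + shift, n2, gens
            )
        out["zerofold"][cls] = ClassSFS(
            cls=cls,
            entries=ctx.theta * w * sel,
            sample_size=n,
            folded=True,
            site_count=1.0,
        )
    return out


def _variant_rows(
    sampled: Dict[MutationClass, ClassSFS],
    site_class: str,
    gene_ids: Sequence[str],
    n: int,
    gc_content: float,
    rng: np.random.Generator,
):
    rows = []
    for cls, sfs in sampled.items():
        for k, count in enumerate(sfs.entries):
            for _ in range(int(count)):
                if cls is MutationClass.WWSS:
                    pair = _WWSS_PAIRS[rng.random() < gc_content]
                else:
                    pair = _WS_PAIRS[rng.integers(len(_WS_PAIRS))]
                ref, alt = pair if rng.random() < 0.5 else pair[::-1]
                rows.append(
                    dict(
                        gene_id=gene_ids[rng.integers(len(gene_ids))],
                        site_class=site_class,
                        ref=ref,
                        alt=alt,
                        minor_count=k + 1,
                        n=n,
                    )
                )
    return rows


# codons avoiding stops under all frame-local edits we make; used for the toy genome
_SAFE_GC_CODON = "GCC"  # alanine, 4-fold third position
_SAFE_AT_CODON = "GCT"


def _write_toy_annotation(
    scenario: SyntheticScenario, out_dir: str, rng: np.random.Generator
) -> Tuple[str, str, str]:
    """Toy single-chromosome genome: FASTA, GFF3 with one CDS per gene, map."""
    n_genes = scenario.n_genes
    gene_len = 300  # nt of CDS per gene
    spacer = 200
    chrom = f"{scenario.name}_chr1"
    seq_parts = []
    gff_lines = ["##gff-version 3"]
    pos = 0
    for g in range(n_genes):
        seq_parts.append(
            "".join(rng.choice(["A", "C", "G", "T"], size=spacer))
        )
        pos += spacer
        start = pos
        # GC4 gradient along the chromosome: early genes AT-rich at 4-fold sites
        gc_frac = (g + 0.5) / n_genes
        codons = np.where(
            rng.random(gene_len // 3) < gc_frac, _SAFE_GC_CODON, _SAFE_AT_CODON
        )
        seq_parts.append("".join(codons))
        pos += gene_len
        gff_lines.append(
            "\t".join(
                [
                    chrom,
                    "toy",
                    "CDS",
                    str(start + 1),
                    str(pos),
                    ".",
                    "+",
                    "0",
                    f"ID=cds{g};Parent={scenario.name}_g{g:04d}",
                ]
            )
        )
    fasta_path = os.path.join(out_dir, f"{scenario.name}_genome.fa")
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        seq = "".join(seq_parts)
        for k in range(0, len(seq), 80):
            fh.write(seq[k : k + 80] + "\n")
    gff_path = os.path.join(out_dir, f"{scenario.name}_genes.gff3")
    with open(gff_path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    # genetic map: smooth increasing cubic-ish map over the chromosome
    length = pos + spacer
    marker_bp = np.linspace(0, length, 25)
    x = marker_bp / 1e6
    cm = 2.0 * x + 15.0 * x**2  # rate rises toward the chromosome end
    map_path = os.path.join(out_dir, f"{scenario.name}_map.tsv")
    pd.DataFrame(
        dict(chromosome=chrom, position_bp=marker_bp.astype(int), position_cM=cm)
    ).to_csv(map_path, sep="\t", index=False)
    return fasta_path, gff_path, map_path


def make_two_species_dataset(
    scenarios: Sequence[SyntheticScenario],
    out_dir: str,
    seed: int = 0,
    grid_points: int = 61,
) -> Dict[str, Dict[str, str]]:
    """Write the full toy bundle for a pair of species scenarios.

    Per species: a variant allele-count TSV, a per-gene callable-site
    table, a per-gene divergence table (Poisson-sampled from the model
    expectations), a toy genome FASTA, a GFF3 CDS annotation and a genetic
    map marker table.  Returns the file paths keyed by species name.
    """
    if len(scenarios) != 2:
        raise ValueError("expected exactly two species scenarios")
    os.makedirs(out_dir, exist_ok=True)
    bundle: Dict[str, Dict[str, str]] = {}
    for k, scn in enumerate(scenarios):
        rng = np.random.default_rng((seed, k))
        paths: Dict[str, str] = {}
        gene_ids = [f"{scn.name}_g{g:04d}" for g in range(scn.n_genes)]
        expected = expected_scenario_sfs(scn, grid_points=grid_points)
        site_totals = {
            "fourfold": scn.n_neutral_sites,
            "zerofold": scn.n_selected_sites,
        }
        rows = []
        for site_class, per_class in expected.items():
            sampled = {
                cls: sample_sfs(
                    sfs, site_totals[site_class], seed=int(rng.integers(2**31))
                )
                for cls, sfs in per_class.items()
            }
            rows.extend(
                _variant_rows(
                    sampled,
                    site_class,
                    gene_ids,
                    scn.ctx.sample_size,
                    scn.ctx.gc_content,
                    rng,
                )
            )
        alleles = pd.DataFrame(rows)
        paths["alleles"] = os.path.join(out_dir, f"{scn.name}_alleles.tsv")
        alleles.to_csv(paths["alleles"], sep="\t", index=False)

        # per-gene callable sites (equal split, remainder on the first genes)
        sites_rows = []
        for site_class, total in site_totals.items():
            base, extra = divmod(int(total), scn.n_genes)
            for g, gid in enumerate(gene_ids):
                sites_rows.append(
                    dict(
                        gene_id=gid,
                        site_class=site_class,
                        n_sites=base + (1 if g < extra else 0),
                    )
                )
        paths["sites"] = os.path.join(out_dir, f"{scn.name}_sites.tsv")
        pd.DataFrame(sites_rows).to_csv(paths["sites"], sep="\t", index=False)

        # per-gene divergence counts from the model expectations
        d0 = expected_divergence(scn.dfe, scn.ctx, scn.t_theta).k_total
        d4 = expected_divergence(
            DFEModel(shape_beta=1.0, mean_gamma=0.0), scn.ctx, scn.t_theta
        ).k_total
        sites = pd.read_csv(paths["sites"], sep="\t")
        s0 = sites[sites.site_class == "zerofold"].set_index("gene_id").n_sites
        s4 = sites[sites.site_class == "fourfold"].set_index("gene_id").n_sites
        div = pd.DataFrame(
            dict(
                gene_id=gene_ids,
                k0=rng.poisson([d0 * s0[g] for g in gene_ids]),
                sites0=[int(s0[g]) for g in gene_ids],
                k4=rng.poisson([d4 * s4[g] for g in gene_ids]),
                sites4=[int(s4[g]) for g in gene_ids],
            )
        )
        paths["divergence"] = os.path.join(out_dir, f"{scn.name}_divergence.tsv")
        div.to_csv(paths["divergence"], sep="\t", index=False)

        paths["fasta"], paths["gff"], paths["map"] = _write_toy_annotation(
            scn, out_dir, rng
        )
        bundle[scn.name] = paths
    return bundle


def default_species_pair(
    n_neutral_sites: int = 1_000_000,
    n_selected_sites: int = 1_000_000,
    n_genes: int = 300,
) -> Tuple[SyntheticScenario, SyntheticScenario]:
    """A small-Ne / large-Ne species pair with a 2.83-fold theta contrast.

    The large-Ne species carries proportionally stronger scaled selection
    (same underlying fitness effects, larger N), a stronger beneficial
    class and stronger gBGC, so it should show lower pi0/pi4 and a higher
    inferred alpha.
    """
    ratio = 2.83
    demog = TwoEpochDemography(size_ratio=2.0, change_time=0.25)
    small = SyntheticScenario(
        name="smallne",
        dfe=DFEModel(
            shape_beta=0.3,
            mean_gamma=-200.0 / ratio,
            beneficial_fraction=0.02,
            beneficial_gamma=10.0 / ratio,
        ),
        ctx=GBGCContext(
            B=1.0 / ratio, kappa=2.0, gc_content=0.472, theta=0.0035, sample_size=20
        ),
        demog=demog,
        n_neutral_sites=n_neutral_sites,
        n_selected_sites=n_selected_sites,
        n_genes=n_genes,
    )
    large = SyntheticScenario(
        name="largene",
        dfe=DFEModel(
            shape_beta=0.3,
            mean_gamma=-200.0,
            beneficial_fraction=0.02,
            beneficial_gamma=10.0,
        ),
        ctx=GBGCContext(
            B=1.0, kappa=2.0, gc_content=0.472, theta=0.0035 * ratio, sample_size=20
        ),
        demog=demog,
        n_neutral_sites=n_neutral_sites,
        n_selected_sites=n_selected_sites,
        n_genes=n_genes,
    )
    return small, large
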