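"""Polymorphism summary statistics from observed allele counts.

Builds folded spectra from per-site minor-allele counts, classifies base
changes as GC-conservative (WWSS) or not, and computes nucleotide
diversity (pi), Watterson's theta and Tajima's D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .models import ClassSFS, MutationClass, SiteClass, SummaryStats

__all__ = [
    "AlleleCountRecord",
    "classify_mutation",
    "folded_sfs_from_counts",
    "summary_stats",
]

_WEAK = frozenset("AT")
_STRONG = frozenset("CG")
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AlleleCountRecord:
    """A biallelic (or monomorphic) site with its folded allele count.

    ``minor_count == 0`` marks a monomorphic site; ``ref_base == alt_base``
    is then allowed (``alt_base`` is ignored).
    """

    gene_id: str
    site_class: SiteClass
    ref_base: str
    alt_base: str
    minor_count: int
    n_chromosomes: int

    def __post_init__(self) -> None:
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError(
                f"invalid base in record: {self.ref_base}/{self.alt_base}"
            )
        if self.minor_count > 0 and self.ref_base == self.alt_base:
            raise ValueError("variant rows need distinct ref and alt bases")
        if not 0 <= self.minor_count <= self.n_chromosomes // 2:
            raise ValueError(
                f"minor_count {self.minor_count} outside 0..n/2 "
                f"(n={self.n_chromosomes})"
            )

    @property
    def is_variant(self) -> bool:
        return self.minor_count > 0


def classify_mutation(ref: str, alt: str) -> MutationClass:
    """WWSS for A<->T and C<->G changes, WS_OR_SW for any weak<->strong change.

    Unpolarized polymorphism data cannot distinguish W->S from S->W, so all
    GC-changing mutations share one class.  Symmetric in argument order.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"invalid bases ({ref}, {alt})")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if (ref in _WEAK) == (alt in _WEAK):
        return MutationClass.WWSS
    return MutationClass.WS_OR_SW


def folded_sfs_from_counts(
    records: Iterable[AlleleCountRecord],
    site_class: Optional[SiteClass] = None,
    wwss_only: bool = False,
) -> ClassSFS:
    """Histogram of minor-allele counts over 1..n/2 plus the monomorphic total.

    ``site_count`` on the returned SFS counts every callable site of the
    class (variant and monomorphic), which is the denominator for per-site
    diversity statistics.  With ``wwss_only`` the GC-changing variants are
    dropped from the spectrum but monomorphic sites are retained.
    """
    records = [
        r for r in records if site_class is None or r.site_class == site_class
    ]
    if not records:
        raise ValueError("no records in the requested site class")
    n_values = {r.n_chromosomes for r in records}
    if len(n_values) != 1:
        raise ValueError(f"records mix sample sizes: {sorted(n_values)}")
    n = n_values.pop()
    counts = np.zeros(n // 2)
    n_sites = 0
    for r in records:
        n_sites += 1
        if not r.is_variant:
            continue
        if wwss_only and classify_mutation(r.ref_base, r.alt_base) is not MutationClass.WWSS:
            continue
        counts[r.minor_count - 1] += 1
    cls = MutationClass.WWSS if wwss_only else MutationClass.COMBINED
    return ClassSFS(
        cls=cls, entries=counts, sample_size=n, folded=True, site_count=n_sites
    )


def _tajima_constants(n: int):
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def summary_stats(sfs: ClassSFS, n: Optional[int] = None) -> SummaryStats:
    """pi, Watterson's theta and Tajima's D from a folded spectrum.

    pi sums the per-site heterozygosity ``2 i (n-i) / (n (n-1))`` over
    minor-count classes; theta_W is ``S / (a_n L)``; D uses the standard
    variance constants and is undefined (None) when there are no
    segregating sites.
    """
    if not sfs.folded:
        raise ValueError("summary_stats expects a folded SFS")
    if n is None:
        n = sfs.sample_size
    if sfs.site_count <= 0:
        raise ValueError("SFS has no sites")
    L = sfs.site_count
    i = np.arange(1, sfs.entries.size + 1)
    pairwise = float(np.sum(sfs.entries * 2.0 * i * (n - i) / (n * (n - 1.0))))
    S = float(sfs.entries.sum())
    a1, e1, e2 = _tajima_constants(n)
    theta_w = S / (a1 * L)
    if S == 0:
        d = None
    else:
        if n < 4:
            raise ValueError("Tajima's D needs n >= 4")
        var = e1 * S + e2 * S * (S - 1.0)
        d = float((pairwise - S / a1) / np.sqrt(var))
    return SummaryStats(
        pi=pairwise / L,
        watterson_theta=theta_w,
        tajimas_d=d,
        n_sites=int(round(L)),
        n_segregating=int(round(S)),
    )
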