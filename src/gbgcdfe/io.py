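"""Readers and writers for the package's tabular formats.

All formats are plain text: tab-separated SFS and allele-count tables,
genetic-map marker tables, per-gene divergence counts, plus a VCF reader
for genotype data.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .models import ClassSFS, MutationClass, SiteClass, SummaryStats
from .summaries import AlleleCountRecord

__all__ = [
    "write_sfs",
    "read_sfs",
    "write_allele_counts",
    "read_allele_counts",
    "read_genetic_map",
    "write_divergence_counts",
    "read_divergence_counts",
    "read_vcf_allele_counts",
    "write_summary_stats",
]


def write_sfs(sfs: ClassSFS, path: str) -> None:
    """Serialize an SFS: header lines then (i, class, expected_count) rows."""
    with open(path, "w") as fh:
        fh.write(f"# folded: {str(sfs.folded).lower()}\n")
        fh.write(f"# n: {sfs.sample_size}\n")
        fh.write(f"# site_count: {sfs.site_count!r}\n")
        fh.write("i\tclass\texpected_count\n")
        for k, v in enumerate(sfs.entries, start=1):
            fh.write(f"{k}\t{sfs.cls.value}\t{v:.12g}\n")


def read_sfs(path: str) -> ClassSFS:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("i\t"):
                rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"no SFS rows in {path}")
    cls = MutationClass(rows[0][1])
    entries = np.array([float(r[2]) for r in rows])
    return ClassSFS(
        cls=cls,
        entries=entries,
        sample_size=int(meta["n"]),
        folded=meta.get("folded", "false") == "true",
        site_count=float(meta.get("site_count", 1.0)),
    )


_ALLELE_COLS = ["gene_id", "site_class", "ref", "alt", "minor_count", "n"]


def write_allele_counts(records: Iterable[AlleleCountRecord], path: str) -> None:
    df = pd.DataFrame(
        [
            (r.gene_id, r.site_class.value, r.ref_base, r.alt_base,
             r.minor_count, r.n_chromosomes)
            for r in records
        ],
        columns=_ALLELE_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_allele_counts(path: str) -> List[AlleleCountRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    missing = set(_ALLELE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-count table misses columns {sorted(missing)}")
    return [
        AlleleCountRecord(
            gene_id=str(row.gene_id),
            site_class=SiteClass(row.site_class),
            ref_base=row.ref,
            alt_base=row.alt,
            minor_count=int(row.minor_count),
            n_chromosomes=int(row.n),
        )
        for row in df.itertuples()
    ]


def read_genetic_map(path: str) -> pd.DataFrame:
    """Marker table with columns chromosome, position_bp, position_cM."""
    df = pd.read_csv(path, sep="\t")
    needed = {"chromosome", "position_bp", "position_cM"}
    if not needed <= set(df.columns):
        raise ValueError(f"genetic map table needs columns {sorted(needed)}")
    return df


_DIV_COLS = ["gene_id", "k0", "sites0", "k4", "sites4"]


def write_divergence_counts(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, columns=_DIV_COLS)


def read_divergence_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_DIV_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"divergence table misses columns {sorted(missing)}")
    return df


def read_vcf_allele_counts(
    vcf_path: str,
    site_classes: Dict[Tuple[str, int], Tuple[str, SiteClass]],
) -> List[AlleleCountRecord]:
    """Allele-count records from a VCF with both variant and invariant rows.

    ``site_classes`` maps (chromosome, 1-based position) to (gene_id,
    site class); positions absent from the map are skipped, as are sites
    with more than two alleles or missing genotype calls (matching the
    usual every-sample-called, biallelic filtering).
    """
    import pysam

    records = []
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            key = (rec.chrom, rec.pos)
            if key not in site_classes:
                continue
            gene_id, site_class = site_classes[key]
            alts = [a for a in (rec.alts or ()) if a not in (None, ".", "<NON_REF>")]
            if len(alts) > 1:
                continue
            alleles = []
            complete = True
            for sample in rec.samples.values():
                gt = sample["GT"]
                if gt is None or any(a is None for a in gt):
                    complete = False
                    break
                alleles.extend(gt)
            if not complete or not alleles:
                continue
            n = len(alleles)
            alt_count = sum(1 for a in alleles if a != 0)
            minor = min(alt_count, n - alt_count)
            if alt_count in (0, n) or not alts:
                records.append(
                    AlleleCountRecord(
                        gene_id=gene_id,
                        site_class=site_class,
                        ref_base=rec.ref,
                        alt_base=rec.ref,
                        minor_count=0,
                        n_chromosomes=n,
                    )
                )
            else:
                records.append(
                    AlleleCountRecord(
                        gene_id=gene_id,
                        site_class=site_class,
                        ref_base=rec.ref,
                        alt_base=alts[0],
                        minor_count=minor,
                        n_chromosomes=n,
                    )
                )
    return records


def write_summary_stats(stats: Dict[str, SummaryStats], path: str) -> None:
    """One row per labelled class: pi, theta_W, Tajima's D, site counts."""
    rows = []
    for label, s in stats.items():
        rows.append(
            dict(
                label=label,
                pi=s.pi,
                watterson_theta=s.watterson_theta,
                tajimas_d=np.nan if s.tajimas_d is None else s.tajimas_d,
                n_sites=s.n_sites,
                n_segregating=s.n_segregating,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
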