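"""Site classification and gene binning.

Codon degeneracy (0-fold / 4-fold sites), GC content at 4-fold sites
(GC4), genetic-map smoothing with a cubic polynomial and its derivative as
the local recombination rate, map-length-per-coding-site (M/C) windows,
and equal-sized tertile binning of genes.

Coordinates are 0-based half-open internally; the GFF3 reader converts
from the 1-based inclusive convention on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "Degeneracy",
    "codon_degeneracy",
    "GeneRecord",
    "GeneticMapModel",
    "fit_genetic_map",
    "recombination_rate_at",
    "window_recombination_rate",
    "window_mc_ratio",
    "tertile_bins",
    "read_cds_annotation",
    "gene_gc4",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"


class Degeneracy:
    ZEROFOLD = "zerofold"
    TWOFOLD_THREEFOLD = "twofold_threefold"
    FOURFOLD = "fourfold"
    STOP_ADJACENT = "stop_adjacent"


_STOPS = set(standard_dna_table.stop_codons)


def _amino_acid(codon: str) -> Optional[str]:
    return standard_dna_table.forward_table.get(codon)


def codon_degeneracy(codon: str, pos: int) -> str:
    """Degeneracy of position ``pos`` (0..2) of ``codon`` (standard code).

    Fourfold iff all three substitutions preserve the amino acid; zerofold
    iff none does (a change to a stop codon counts as a change).  Stop
    codons themselves are flagged ``stop_adjacent`` and excluded from
    analysis, as are two/threefold positions.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if pos not in (0, 1, 2):
        raise ValueError("pos must be 0, 1 or 2")
    if codon in _STOPS:
        return Degeneracy.STOP_ADJACENT
    aa = _amino_acid(codon)
    synonymous = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in _STOPS and _amino_acid(alt) == aa:
            synonymous += 1
    if synonymous == 3:
        return Degeneracy.FOURFOLD
    if synonymous == 0:
        return Degeneracy.ZEROFOLD
    return Degeneracy.TWOFOLD_THREEFOLD


@dataclass
class GeneRecord:
    """A protein-coding gene with its CDS segments (0-based half-open)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    cds_segments: List[Tuple[int, int]] = field(default_factory=list)
    gc4: float = np.nan
    n_coding_sites: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        segs = sorted(self.cds_segments)
        for (a, b), (c, d) in zip(segs, segs[1:]):
            if c < b:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        if segs and not self.n_coding_sites:
            self.n_coding_sites = sum(b - a for a, b in segs)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def coding_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in transcript orientation (reverse-complemented on '-')."""
        parts = [chrom_seq[a:b] for a, b in sorted(self.cds_segments)]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        if len(seq) % 3:
            raise ValueError(
                f"CDS of {self.gene_id} is not a multiple of 3 ({len(seq)} nt)"
            )
        return seq.upper()


def gene_gc4(gene: GeneRecord, chrom_seq: str) -> float:
    """GC content at the gene's 4-fold degenerate sites (NaN if none)."""
    seq = gene.coding_sequence(chrom_seq)
    gc = total = 0
    for k in range(0, len(seq) - 2, 3):
        codon = seq[k : k + 3]
        if any(b not in _BASES for b in codon):
            logger.info("skipping ambiguous codon %s in %s", codon, gene.gene_id)
            continue
        if codon_degeneracy(codon, 2) == Degeneracy.FOURFOLD:
            total += 1
            gc += codon[2] in "GC"
    return gc / total if total else np.nan


@dataclass(frozen=True)
class GeneticMapModel:
    """Cubic fit of map position (cM) against physical position (Mb)."""

    chromosome: str
    coefficients: tuple  # ascending powers, numpy polynomial convention
    fit_r2: float
    phys_range: Tuple[float, float]  # bp

    def map_position(self, position_bp: float) -> float:
        self._check_range(position_bp)
        return float(
            np.polynomial.polynomial.polyval(position_bp / 1e6, self.coefficients)
        )

    def derivative_cm_per_mb(self, position_bp: float) -> float:
        self._check_range(position_bp)
        der = np.polynomial.polynomial.polyder(self.coefficients)
        return float(np.polynomial.polynomial.polyval(position_bp / 1e6, der))

    def _check_range(self, position_bp: float) -> None:
        lo, hi = self.phys_range
        if not lo <= position_bp <= hi:
            raise ValueError(
                f"position {position_bp} outside marker range "
                f"[{lo}, {hi}] on {self.chromosome}"
            )


def fit_genetic_map(markers: pd.DataFrame, chromosome: str) -> GeneticMapModel:
    """Least-squares cubic of cM against Mb for one chromosome's markers.

    ``markers`` needs columns ``chromosome``, ``position_bp``,
    ``position_cM``.
    """
    sub = markers[markers["chromosome"] == chromosome]
    if len(sub) < 4:
        raise ValueError(f"need >= 4 markers on {chromosome}, got {len(sub)}")
    x = sub["position_bp"].to_numpy(float) / 1e6
    y = sub["position_cM"].to_numpy(float)
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg=3)
    pred = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GeneticMapModel(
        chromosome=chromosome,
        coefficients=tuple(coeffs),
        fit_r2=r2,
        phys_range=(float(sub["position_bp"].min()), float(sub["position_bp"].max())),
    )


def recombination_rate_at(map_model: GeneticMapModel, position_bp: float) -> float:
    """Local recombination rate (cM/Mb): derivative of the cubic, clamped >= 0."""
    rate = map_model.derivative_cm_per_mb(position_bp)
    if rate < 0:
        logger.warning(
            "negative map derivative %.4f at %s:%d clamped to 0",
            rate,
            map_model.chromosome,
            position_bp,
        )
        return 0.0
    return rate


def _clip_to_range(map_model: GeneticMapModel, pos: float) -> float:
    lo, hi = map_model.phys_range
    return min(max(pos, lo), hi)


def window_recombination_rate(
    gene: GeneRecord, map_model: GeneticMapModel, half_width: float = 5e5
) -> float:
    """Mean of the rates at the window midpoint and its two +-half_width boundaries."""
    mid = gene.midpoint
    points = [
        _clip_to_range(map_model, mid - half_width),
        _clip_to_range(map_model, mid),
        _clip_to_range(map_model, mid + half_width),
    ]
    return float(np.mean([recombination_rate_at(map_model, p) for p in points]))


def _coding_sites_in_window(
    genes: Sequence[GeneRecord], chromosome: str, lo: float, hi: float
) -> int:
    total = 0
    for g in genes:
        if g.chromosome != chromosome:
            continue
        for a, b in g.cds_segments:
            total += max(0, min(b, hi) - max(a, lo))
    return int(total)


def window_mc_ratio(
    gene: GeneRecord,
    map_model: GeneticMapModel,
    annotation: Sequence[GeneRecord],
    half_width: float = 5e5,
) -> float:
    """Map length per coding site (M/C) in a +-half_width window around the gene.

    M is the fitted map length between the window boundaries (clamped to be
    nonnegative and truncated at the marker range / chromosome end); C is
    the number of coding sites any annotated gene contributes to the
    window.  Returns NaN when C is 0.
    """
    mid = gene.midpoint
    lo = _clip_to_range(map_model, mid - half_width)
    hi = _clip_to_range(map_model, mid + half_width)
    m_len = max(0.0, map_model.map_position(hi) - map_model.map_position(lo))
    c = _coding_sites_in_window(annotation, gene.chromosome, lo, hi)
    if c == 0:
        logger.warning("window around %s has no coding sites", gene.gene_id)
        return np.nan
    return m_len / c


def tertile_bins(
    genes: Sequence[GeneRecord], key: str = "GC4"
) -> List[List[GeneRecord]]:
    """Split genes into three equal-sized (+-1) bins by ascending key.

    ``key`` is ``"GC4"`` or ``"MC"`` (the latter requires an ``mc_ratio``
    attribute set on the gene records).  Genes with an undefined key are
    excluded with a log message; ties are broken by stable gene_id order.
    """
    key = key.upper()
    if key == "GC4":
        getter = lambda g: g.gc4  # noqa: E731
    elif key == "MC":
        getter = lambda g: getattr(g, "mc_ratio", np.nan)  # noqa: E731
    else:
        raise ValueError("key must be 'GC4' or 'MC'")
    usable = [g for g in genes if np.isfinite(getter(g))]
    dropped = len(list(genes)) - len(usable)
    if dropped:
        logger.info("tertile_bins: excluded %d genes with undefined %s", dropped, key)
    if len(usable) < 3:
        raise ValueError("need at least 3 genes with a defined key")
    usable.sort(key=lambda g: g.gene_id)  # stable tie order
    usable.sort(key=getter)
    return [list(part) for part in np.array_split(np.array(usable, dtype=object), 3)]


def read_cds_annotation(gff_path: str) -> List[GeneRecord]:
    """Genes with CDS segments from a GFF3 file (1-based inclusive on disk)."""
    genes: Dict[str, GeneRecord] = {}
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("Parent") or attr.get("ID") or attr.get("gene_id")
            if gid is None:
                raise ValueError(f"CDS feature without identifier: {line!r}")
            seg = (int(start) - 1, int(end))
            if gid not in genes:
                genes[gid] = GeneRecord(
                    gene_id=gid,
                    chromosome=chrom,
                    start=seg[0],
                    end=seg[1],
                    strand=strand,
                    cds_segments=[seg],
                )
            else:
                g = genes[gid]
                g.cds_segments.append(seg)
                g.start = min(g.start, seg[0])
                g.end = max(g.end, seg[1])
                g.n_coding_sites = sum(b - a for a, b in g.cds_segments)
    return list(genes.values())
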