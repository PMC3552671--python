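"""Divergent (head-to-head) gene-pair discovery and distance categories.

A divergent pair is two genes on the same chromosome and opposite strands
whose transcription proceeds away from the shared inter-TSS region, with
TSSs separated by less than ``max_distance`` bp (1000 by default).  By
convention the minus-strand gene is drawn on the left: pairs whose
minus-strand TSS lies right of the plus-strand TSS (interleaved
transcripts) are excluded, since the NEG-MID-POS window model assumes
that layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import Gene, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "GenePair",
    "find_divergent_pairs",
    "select_isolated_genes",
    "assign_distance_category",
    "DEFAULT_CATEGORY_BOUNDARIES",
]

DEFAULT_CATEGORY_BOUNDARIES = (200, 400, 600, 800, 1000)


@dataclass(frozen=True)
class GenePair:
    """A head-to-head pair: minus-strand gene left, plus-strand gene right."""

    gene_pos: Gene
    gene_neg: Gene
    distance: int
    midpoint: int
    category_index: int | None = None

    def __post_init__(self) -> None:
        if self.gene_pos.strand != "+" or self.gene_neg.strand != "-":
            raise ValueError("gene_pos must be on +, gene_neg on -")
        if self.gene_pos.chrom != self.gene_neg.chrom:
            raise ValueError("pair genes must share a chromosome")
        if self.distance != abs(self.gene_pos.tss - self.gene_neg.tss):
            raise ValueError("distance inconsistent with TSS coordinates")

    @property
    def tss_neg(self) -> int:
        return self.gene_neg.tss

    @property
    def tss_pos(self) -> int:
        return self.gene_pos.tss


def find_divergent_pairs(genes: GeneSet, max_distance: int = 1000) -> list[GenePair]:
    """All divergent head-to-head pairs with inter-TSS distance < max_distance.

    Isoform pairs producing an identical (gene-locus pair, distance)
    combination are collapsed to one representative; isoforms giving
    distinct distances each yield their own pair.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    pairs: list[GenePair] = []
    seen: set[tuple] = set()
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.tss, g.id))
        plus = [g for g in chrom_genes if g.strand == "+"]
        minus = [g for g in chrom_genes if g.strand == "-"]
        for gp in plus:
            for gm in minus:
                if gm.tss > gp.tss:
                    if abs(gm.tss - gp.tss) < max_distance:
                        logger.debug(
                            "excluding interleaved pair %s/%s (tss_neg > tss_pos)",
                            gm.id, gp.id,
                        )
                    continue
                dist = gp.tss - gm.tss
                if dist >= max_distance:
                    continue
                key = (chrom, gm.tss, gp.tss, dist)
                if key in seen:
                    continue
                seen.add(key)
                pairs.append(
                    GenePair(
                        gene_pos=gp,
                        gene_neg=gm,
                        distance=dist,
                        midpoint=(gm.tss + gp.tss) // 2,
                    )
                )
    return pairs


def select_isolated_genes(
    genes: GeneSet,
    min_transcript_len: int = 10_000,
    isolation_radius: int = 10_000,
) -> GeneSet:
    """Genes long enough and far enough from neighbours for clean profiles.

    Keeps genes with transcript length > ``min_transcript_len`` whose TSS
    has no other gene's TSS or transcript interval within
    ``isolation_radius`` bp.
    """
    kept = []
    gene_list = list(genes)
    for g in gene_list:
        if g.length <= min_transcript_len:
            continue
        lo, hi = g.tss - isolation_radius, g.tss + isolation_radius
        crowded = False
        for other in gene_list:
            if other is g or other.chrom != g.chrom:
                continue
            if lo <= other.tss <= hi:
                crowded = True
                break
            if other.transcript_start < hi and other.transcript_end > lo:
                crowded = True
                break
        if not crowded:
            kept.append(g)
    return GeneSet(kept)


def assign_distance_category(
    pair: GenePair,
    boundaries: tuple[int, ...] = DEFAULT_CATEGORY_BOUNDARIES,
) -> int:
    """1-based distance category: smallest k with distance < boundaries[k-1]."""
    if pair.distance >= boundaries[-1]:
        raise ValueError(
            f"distance {pair.distance} >= last boundary {boundaries[-1]}"
        )
    for k, b in enumerate(boundaries, start=1):
        if pair.distance < b:
            return k
    raise AssertionError("unreachable")
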