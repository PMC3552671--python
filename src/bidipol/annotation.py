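"""Downstream annotation of categorized promoters.

Two read-outs of regulatory function: expression tallies per promoter
category (consuming a precomputed expressed/unexpressed flag table), and
assignment of transcription-factor peak centers to the left gene body /
inter-TSS middle / right gene body zones around each pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PeakSet

__all__ = ["CategoryTally", "TfAssignment", "tally_expression", "assign_tf_sites"]

CATEGORIES = ("double", "left", "right", "centre")


@dataclass
class CategoryTally:
    category: str
    n_pairs: int = 0
    n_left_expressed: int = 0
    n_right_expressed: int = 0
    n_both_expressed: int = 0

    def validate(self) -> None:
        if not (self.n_both_expressed
                <= min(self.n_left_expressed, self.n_right_expressed)
                <= self.n_pairs):
            raise ValueError("inconsistent tally")


@dataclass
class TfAssignment:
    category: str
    n_left_body: int = 0
    n_middle: int = 0
    n_right_body: int = 0


def tally_expression(pairs, flags: dict):
    """Per-category counts of expressed left / right / both genes.

    Parameters
    ----------
    pairs
        Iterable of (category, left_gene_id, right_gene_id); the left
        gene is the minus-strand gene by the package's convention.
    flags
        Mapping gene id -> bool (expressed).  Pairs with a gene missing
        from the table are excluded and counted as dropped.

    Returns
    -------
    (tallies, n_dropped) where tallies maps category -> CategoryTally.
    """
    tallies = {c: CategoryTally(category=c) for c in CATEGORIES}
    n_dropped = 0
    for category, left_id, right_id in pairs:
        if category not in tallies:
            raise ValueError(f"unknown promoter category {category!r}")
        if left_id not in flags or right_id not in flags:
            n_dropped += 1
            continue
        t = tallies[category]
        t.n_pairs += 1
        le, re = bool(flags[left_id]), bool(flags[right_id])
        t.n_left_expressed += le
        t.n_right_expressed += re
        t.n_both_expressed += le and re
    for t in tallies.values():
        t.validate()
    return tallies, n_dropped


def assign_tf_sites(
    chrom: str,
    tss_neg: int,
    tss_pos: int,
    peaks: PeakSet,
    category: str = "double",
    body_extension: int = 500,
) -> TfAssignment:
    """Count TF peak centers per zone around one divergent pair.

    Zones (half-open, left-to-right): left gene body
    ``[tss_neg - body_extension, tss_neg)``, middle ``[tss_neg, tss_pos)``,
    right gene body ``[tss_pos, tss_pos + body_extension)``.  A center on
    a boundary goes to the rightward zone; centers outside all zones are
    ignored.  With coincident TSSs the middle zone is empty.
    """
    if tss_neg > tss_pos:
        raise ValueError("tss_neg must not exceed tss_pos")
    centers = peaks.centers_on(chrom)
    left = int(np.sum((centers >= tss_neg - body_extension) & (centers < tss_neg)))
    middle = int(np.sum((centers >= tss_neg) & (centers < tss_pos)))
    right = int(np.sum((centers >= tss_pos) & (centers < tss_pos + body_extension)))
    return TfAssignment(category=category, n_left_body=left, n_middle=middle,
                        n_right_body=right)
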