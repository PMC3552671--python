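"""Binned coverage profiles anchored on transcription start sites.

All genomic coordinates are 0-based half-open; conversions to and from
1-based formats happen only at file boundaries (:mod:`bidipol.io`).

A :class:`BinnedProfile` holds integer fragment counts over a window of
fixed-width bins.  Profiles built for a divergent gene pair additionally
carry, per bin, a region label (``NEG`` — transcript of the minus-strand
gene, ``MID`` — between the two TSSs, ``POS`` — transcript of the
plus-strand gene) and the distances to both TSS bins, which is everything
the two-promoter Poisson model needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

NEG = "NEG"
MID = "MID"
POS = "POS"
NA = "NA"

REGION_LABELS = (NEG, MID, POS, NA)


@dataclass
class BinnedProfile:
    """Integer fragment counts in fixed-width bins over a genomic window.

    Parameters
    ----------
    chrom, start, end
        Window coordinates (0-based half-open); ``end - start`` must be a
        multiple of ``bin_size``.
    bin_size
        Bin width in bp (20 by default throughout the package).
    counts
        Non-negative integer counts, one per bin.
    region_labels
        Optional per-bin label in ``{NEG, MID, POS, NA}`` (pair windows).
    distances
        Optional ``(n_bins, 2)`` array: column 0 is the distance (bp) of
        each bin to the plus-strand TSS bin, column 1 to the minus-strand
        TSS bin.  Distances are measured between bin indices, so the TSS
        bin itself is at distance 0.
    tss_bins
        Optional ``(tss_bin_neg, tss_bin_pos)`` bin indices.  For a
        single-gene profile both entries equal the TSS bin index.
    """

    chrom: str
    start: int
    end: int
    bin_size: int
    counts: np.ndarray
    region_labels: np.ndarray | None = None
    distances: np.ndarray | None = None
    tss_bins: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted window [{self.start}, {self.end})")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if (self.end - self.start) % self.bin_size != 0:
            raise ValueError("window length must be divisible by bin_size")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n_bins,):
            raise ValueError(
                f"counts has shape {self.counts.shape}, expected ({self.n_bins},)"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels, dtype="U3")
            if self.region_labels.shape != (self.n_bins,):
                raise ValueError("region_labels length mismatch")
            bad = set(np.unique(self.region_labels)) - set(REGION_LABELS)
            if bad:
                raise ValueError(f"unknown region labels: {sorted(bad)}")
        if self.distances is not None:
            self.distances = np.asarray(self.distances, dtype=float)
            if self.distances.shape != (self.n_bins, 2):
                raise ValueError("distances must have shape (n_bins, 2)")
            if (self.distances < 0).any():
                raise ValueError("distances must be non-negative")
        if self.tss_bins is not None:
            i_neg, i_pos = self.tss_bins
            if not (0 <= i_neg < self.n_bins and 0 <= i_pos < self.n_bins):
                raise ValueError("tss_bins outside the window")
            if i_neg > i_pos:
                raise ValueError("tss_bin_neg must not exceed tss_bin_pos")

    @property
    def n_bins(self) -> int:
        return (self.end - self.start) // self.bin_size

    def bin_starts(self) -> np.ndarray:
        return self.start + self.bin_size * np.arange(self.n_bins)

    def with_counts(self, counts: np.ndarray) -> "BinnedProfile":
        """Return a copy of this profile geometry carrying new counts."""
        return BinnedProfile(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            bin_size=self.bin_size,
            counts=np.asarray(counts),
            region_labels=None if self.region_labels is None else self.region_labels.copy(),
            distances=None if self.distances is None else self.distances.copy(),
            tss_bins=self.tss_bins,
        )


def _snap_distance(distance: int, bin_size: int) -> int:
    if distance % bin_size != 0:
        snapped = (distance // bin_size) * bin_size
        warnings.warn(
            f"inter-TSS distance {distance} is not a multiple of bin_size "
            f"{bin_size}; rounded down to {snapped}",
            stacklevel=3,
        )
        return snapped
    return distance


def pair_geometry(
    distance: int,
    flank: int = 2000,
    bin_size: int = 20,
    chrom: str = "chrS",
    start: int = 0,
) -> BinnedProfile:
    """Build the labelled zero-count window for a divergent gene pair.

    The window spans ``flank`` bp beyond each TSS bin.  Bins up to and
    including the minus-strand TSS bin are labelled ``NEG``, bins from the
    plus-strand TSS bin onward ``POS``, bins strictly between the TSS bins
    ``MID``.  When the two TSSs fall in the same bin the MID region is
    empty and the shared bin is labelled ``NEG`` (the expected count is
    identical under all three branches at distance 0, so the choice is
    purely a labelling convention).

    Parameters
    ----------
    distance
        Inter-TSS distance in bp; rounded down to a bin multiple with a
        warning if needed.
    flank
        Window extent in bp beyond each TSS bin (default 2000).
    """
    if flank <= 0 or flank % bin_size != 0:
        raise ValueError("flank must be a positive multiple of bin_size")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    distance = _snap_distance(int(distance), bin_size)
    d_bins = distance // bin_size
    n_flank = flank // bin_size
    i_neg = n_flank
    i_pos = i_neg + d_bins
    n = i_pos + n_flank + 1

    idx = np.arange(n)
    labels = np.full(n, MID, dtype="U3")
    labels[idx <= i_neg] = NEG
    labels[idx >= i_pos] = POS
    if d_bins == 0:
        labels[i_neg] = NEG

    distances = np.empty((n, 2), dtype=float)
    distances[:, 0] = np.abs(idx - i_pos) * bin_size
    distances[:, 1] = np.abs(idx - i_neg) * bin_size

    return BinnedProfile(
        chrom=chrom,
        start=start,
        end=start + n * bin_size,
        bin_size=bin_size,
        counts=np.zeros(n, dtype=np.int64),
        region_labels=labels,
        distances=distances,
        tss_bins=(i_neg, i_pos),
    )


def single_gene_geometry(
    flank: int = 2000,
    bin_size: int = 20,
    chrom: str = "chrS",
    start: int = 0,
) -> BinnedProfile:
    """Zero-count TSS-centred window for one plus-strand-oriented gene.

    The TSS bin sits at index ``flank // bin_size``; bins to its left are
    the promoter (upstream) side, bins to its right the transcript side.
    """
    if flank <= 0 or flank % bin_size != 0:
        raise ValueError("flank must be a positive multiple of bin_size")
    n_flank = flank // bin_size
    n = 2 * n_flank + 1
    i_tss = n_flank
    return BinnedProfile(
        chrom=chrom,
        start=start,
        end=start + n * bin_size,
        bin_size=bin_size,
        counts=np.zeros(n, dtype=np.int64),
        tss_bins=(i_tss, i_tss),
    )


def mirror_profile(profile: BinnedProfile) -> BinnedProfile:
    """Reverse a single-gene profile so its transcript extends leftward."""
    if profile.tss_bins is None:
        raise ValueError("profile has no TSS bin to mirror around")
    i_neg, i_pos = profile.tss_bins
    n = profile.n_bins
    return BinnedProfile(
        chrom=profile.chrom,
        start=profile.start,
        end=profile.end,
        bin_size=profile.bin_size,
        counts=profile.counts[::-1].copy(),
        tss_bins=(n - 1 - i_pos, n - 1 - i_neg),
    )
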