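"""Reading alignments, annotations and peak files; binned count profiles.

Reads are extended to fixed-length fragments from their 5' end (200 bp by
default, matching standard ChIP-seq fragment-size handling) and assigned
to fixed-width bins either by fragment midpoint (default; each fragment is
counted exactly once, keeping bin counts compatible with the Poisson
independence the promoter model assumes) or by overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import BinnedProfile

__all__ = [
    "Fragment",
    "FragmentSet",
    "Gene",
    "GeneSet",
    "PeakSet",
    "load_fragments",
    "bin_counts",
    "load_genes",
    "load_peaks",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad fragment interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


class FragmentSet:
    """Extended-read fragments, stored column-wise for fast binning."""

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"fragment table needs columns {sorted(required)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.end), row.strand)

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    @classmethod
    def from_fragments(cls, fragments) -> "FragmentSet":
        rows = [(f.chrom, f.start, f.end, f.strand) for f in fragments]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"]))


@dataclass(frozen=True)
class Gene:
    """One transcript with its TSS derived from strand.

    ``tss`` equals ``transcript_start`` on the plus strand and
    ``transcript_end`` on the minus strand (0-based half-open internally,
    so the minus-strand TSS is the end coordinate).
    """

    id: str
    chrom: str
    strand: str
    tss: int
    transcript_start: int
    transcript_end: int
    expressed: bool | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for gene {self.id}")
        if self.transcript_end <= self.transcript_start:
            raise ValueError(f"empty transcript for gene {self.id}")
        expected = self.transcript_start if self.strand == "+" else self.transcript_end
        if self.tss != expected:
            raise ValueError(f"TSS of {self.id} inconsistent with strand")

    @property
    def length(self) -> int:
        return self.transcript_end - self.transcript_start


class GeneSet:
    def __init__(self, genes):
        genes = list(genes)
        ids = [g.id for g in genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transcript ids: {dup}")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, i):
        return self.genes[i]


@dataclass
class PeakSet:
    """Sorted enriched-region intervals with precomputed centers."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "center"]))

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "center"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        self.df = self.df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def centers_on(self, chrom: str) -> np.ndarray:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["center"].to_numpy(dtype=np.int64)


# ---------------------------------------------------------------------------
# loaders


def load_fragments(path, extension_len: int = 200) -> FragmentSet:
    """Load a BED6 read file, replacing each read by a fixed-length fragment.

    Each read is anchored at its 5' end and extended ``extension_len`` bp in
    the read's strand direction; plus-strand reads keep their start, minus-
    strand reads keep their end.  Fragments running past the chromosome
    start are clamped to 0 with a warning.
    """
    if extension_len <= 0:
        raise ValueError("extension_len must be positive")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError(
            f"{path}: BED6 required for reads (strand column missing; "
            f"got {df.shape[1]} columns)"
        )
    chrom = df[0].astype(str)
    start = df[1].astype(np.int64)
    end = df[2].astype(np.int64)
    strand = df[5].astype(str)
    bad = ~strand.isin(["+", "-"])
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ValueError(f"{path}: missing/invalid strand on line {line}")

    new_start = np.where(strand == "+", start, end - extension_len)
    new_end = new_start + extension_len
    clamped = new_start < 0
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} fragment(s) clamped at chromosome start",
            stacklevel=2,
        )
        new_start = np.maximum(new_start, 0)
    out = pd.DataFrame(
        {"chrom": chrom, "start": new_start, "end": new_end, "strand": strand}
    )
    return FragmentSet(out)


def bin_counts(
    fragments: FragmentSet,
    window: tuple[str, int, int],
    bin_size: int = 20,
    assignment: str = "midpoint",
) -> BinnedProfile:
    """Count fragments per fixed-width bin over a genomic window.

    Under ``midpoint`` assignment (default) each fragment increments the
    single bin containing its midpoint; under ``overlap`` it increments
    every bin it intersects.
    """
    chrom, start, end = window
    if end <= start:
        raise ValueError("empty window")
    if (end - start) % bin_size != 0:
        raise ValueError("window length must be divisible by bin_size")
    if assignment not in ("midpoint", "overlap"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    n = (end - start) // bin_size
    counts = np.zeros(n, dtype=np.int64)
    sub = fragments.on_chrom(chrom)
    if len(sub):
        fs = sub["start"].to_numpy(np.int64)
        fe = sub["end"].to_numpy(np.int64)
        if assignment == "midpoint":
            mid = (fs + fe) // 2
            inside = (mid >= start) & (mid < end)
            idx = (mid[inside] - start) // bin_size
            np.add.at(counts, idx, 1)
        else:
            lo = np.clip((fs - start) // bin_size, 0, n)
            hi = np.clip(-(-(fe - start) // bin_size), 0, n)  # ceil division
            for a, b in zip(lo, hi):
                if b > a:
                    counts[a:b] += 1
    return BinnedProfile(chrom=chrom, start=start, end=end, bin_size=bin_size, counts=counts)


def _genes_from_bed12(path) -> list[Gene]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED needs >= 6 columns for gene annotation")
    genes = []
    for ln, row in enumerate(df.itertuples(index=False), start=1):
        chrom, s, e, name, _, strand = row[0], int(row[1]), int(row[2]), row[3], row[4], row[5]
        if strand not in "+-":
            raise ValueError(f"{path}: unknown strand {strand!r} on line {ln}")
        tss = s if strand == "+" else e
        genes.append(Gene(id=name, chrom=chrom, strand=strand, tss=tss,
                          transcript_start=s, transcript_end=e))
    return genes


def _genes_from_gtf(path) -> list[Gene]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for feat in db.features_of_type("transcript"):
        if feat.strand not in "+-":
            raise ValueError(f"{path}: unknown strand {feat.strand!r} for {feat.id}")
        # GTF is 1-based closed; normalize to 0-based half-open.
        s, e = feat.start - 1, feat.end
        tss = s if feat.strand == "+" else e
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        genes.append(Gene(id=tid, chrom=feat.seqid, strand=feat.strand, tss=tss,
                          transcript_start=s, transcript_end=e))
    return genes


def load_genes(path) -> GeneSet:
    """Load one Gene per transcript from GTF or BED annotation.

    Format is chosen by extension (.gtf/.gff -> GTF, otherwise BED).
    GTF coordinates (1-based closed) are normalized to the internal
    0-based half-open convention.  Duplicate transcript ids are rejected.
    """
    p = str(path)
    if p.endswith((".gtf", ".gff", ".gff3")):
        genes = _genes_from_gtf(path)
    else:
        genes = _genes_from_bed12(path)
    return GeneSet(genes)


def load_peaks(path) -> PeakSet:
    """Load BED3+ enriched regions; centers are floor((start+end)/2)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return PeakSet()
    if df.shape[1] < 3:
        raise ValueError(f"{path}: peaks need >= 3 BED columns")
    start = df[1].astype(np.int64)
    end = df[2].astype(np.int64)
    if (start >= end).any():
        ln = int((start >= end).idxmax()) + 1
        raise ValueError(f"{path}: start >= end on line {ln}")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": start,
            "end": end,
            "center": (start + end) // 2,
        }
    )
    return PeakSet(out)


# ---------------------------------------------------------------------------
# bedGraph round trip


def write_bedgraph(profile: BinnedProfile, path) -> None:
    starts = profile.bin_starts()
    df = pd.DataFrame(
        {
            "chrom": profile.chrom,
            "start": starts,
            "end": starts + profile.bin_size,
            "count": profile.counts,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> BinnedProfile:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "count"])
    if df["chrom"].nunique() != 1:
        raise ValueError("bedGraph profile must cover a single chromosome")
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1:
        raise ValueError("bedGraph profile must have uniform bin width")
    return BinnedProfile(
        chrom=str(df["chrom"].iloc[0]),
        start=int(df["start"].iloc[0]),
        end=int(df["end"].iloc[-1]),
        bin_size=int(widths[0]),
        counts=df["count"].to_numpy(np.int64),
    )
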