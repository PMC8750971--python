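"""Genomic window grids and fragment counting.

The CNI pipeline operates on a fixed grid of autosomal windows.  Counting
happens at "small" resolution (0.55 Mbp tiles by default); groups of
``condense_factor`` consecutive small windows on the same chromosome are
later averaged into "condensed" windows (~5.5 Mbp) before Z-scoring.

Fragments are counted by midpoint: every fragment falls in at most one
window, so total counts are conserved.  Only short fragments
(insert size strictly below 170 bp by default) enter the count, because
tumor-derived cfDNA is enriched in the sub-mononucleosomal size range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

SMALL_WINDOW_BP = 550_000
CONDENSE_FACTOR = 10
MAX_FRAGMENT_LENGTH = 170  # strict upper bound (exclusive)
DEFAULT_MAPQ_MIN = 30

#: column order of the window annotation table
WINDOW_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "group"]


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned cfDNA fragment in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class WindowSet:
    """Ordered, non-overlapping genomic windows with GC/mappability annotations.

    ``table`` columns: chrom, start, end, gc, mappability, group.  ``group``
    is the 0-based index of the condensed window a small window belongs to,
    or -1 for trailing small windows on a chromosome that do not complete a
    full group of ``condense_factor`` (they are counted but excluded from
    condensation).
    """

    table: pd.DataFrame
    resolution: str = "small"
    condense_factor: int = CONDENSE_FACTOR

    def __post_init__(self) -> None:
        missing = [c for c in WINDOW_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"window table missing columns: {missing}")
        if self.resolution not in ("small", "condensed"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        t = self.table
        if (t["start"] >= t["end"]).any():
            raise ValueError("window start must be < end")
        for col in ("gc", "mappability"):
            bad = ~t[col].between(0.0, 1.0)
            if bad.any():
                raise ValueError(f"{col} outside [0, 1] in {int(bad.sum())} windows")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> pd.Index:
        t = self.table
        return pd.Index(
            t["chrom"].astype(str) + ":" + t["start"].astype(str) + "-" + t["end"].astype(str),
            name="window",
        )

    @property
    def n_condensed(self) -> int:
        g = self.table["group"]
        return int(g[g >= 0].nunique())

    def condensed_ids(self) -> pd.Index:
        """Window identifiers of the condensed grid, in group order."""
        t = self.table[self.table["group"] >= 0]
        agg = t.groupby("group", sort=True).agg(
            chrom=("chrom", "first"), start=("start", "min"), end=("end", "max")
        )
        return pd.Index(
            agg["chrom"].astype(str)
            + ":"
            + agg["start"].astype(str)
            + "-"
            + agg["end"].astype(str),
            name="window",
        )

    def condensed_windows(self) -> "WindowSet":
        """The condensed-resolution WindowSet (mean annotations per group)."""
        t = self.table[self.table["group"] >= 0]
        agg = t.groupby("group", sort=True).agg(
            chrom=("chrom", "first"),
            start=("start", "min"),
            end=("end", "max"),
            gc=("gc", "mean"),
            mappability=("mappability", "mean"),
        )
        agg = agg.reset_index(drop=True)
        agg["group"] = np.arange(len(agg))
        return WindowSet(agg[WINDOW_COLUMNS], resolution="condensed", condense_factor=1)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, resolution: str = "small", condense_factor: int = CONDENSE_FACTOR) -> "WindowSet":
        t = pd.read_csv(path, sep="\t")
        if "group" not in t.columns:
            t["group"] = -1
        return cls(t[WINDOW_COLUMNS], resolution=resolution, condense_factor=condense_factor)


def build_windows(
    chrom_sizes: Mapping[str, int],
    small_window_bp: int = SMALL_WINDOW_BP,
    condense_factor: int = CONDENSE_FACTOR,
    gc: np.ndarray | None = None,
    mappability: np.ndarray | None = None,
) -> WindowSet:
    """Tile each chromosome with contiguous ``small_window_bp`` windows.

    A trailing remainder shorter than ``small_window_bp`` is dropped.  Small
    windows that do not complete a group of ``condense_factor`` on their
    chromosome get group -1 (excluded from condensation).  ``gc`` and
    ``mappability`` arrays, if given, must match the total window count;
    otherwise both default to 0.5 / 1.0 placeholders to be overwritten by an
    annotation source.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    if small_window_bp <= 0 or condense_factor <= 0:
        raise ValueError("small_window_bp and condense_factor must be positive")
    rows = []
    group_offset = 0
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
        n_small = size // small_window_bp
        n_groups = n_small // condense_factor
        for i in range(n_small):
            group = group_offset + i // condense_factor if i // condense_factor < n_groups else -1
            rows.append(
                (chrom, i * small_window_bp, (i + 1) * small_window_bp, 0.5, 1.0, group)
            )
        group_offset += n_groups
    table = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    if gc is not None:
        if len(gc) != len(table):
            raise ValueError("gc annotation length mismatch")
        table["gc"] = np.asarray(gc, dtype=float)
    if mappability is not None:
        if len(mappability) != len(table):
            raise ValueError("mappability annotation length mismatch")
        table["mappability"] = np.asarray(mappability, dtype=float)
    return WindowSet(table, resolution="small", condense_factor=condense_factor)


def read_fragments(path, format: str = "bed") -> Iterator[FragmentRecord]:
    """Stream fragment records from a BED-like file (chrom, start, end, [name]).

    Coordinates are 0-based half-open.  Malformed lines raise a ValueError
    naming the offending line number.
    """
    if format not in ("bed", "tsv"):
        raise ValueError(f"unknown fragment format {format!r}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start coordinate")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start} >= {end})")
            yield FragmentRecord(chrom, start, end)


def write_fragments(fragments: Iterable[FragmentRecord], path) -> None:
    """Write fragments as 4-column BED (chrom, start, end, name)."""
    with open(path, "w") as fh:
        for i, frag in enumerate(fragments):
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\tf{i}\n")


def filter_short_fragments(
    fragments: Iterable[FragmentRecord], max_length_exclusive: int = MAX_FRAGMENT_LENGTH
) -> Iterator[FragmentRecord]:
    """Keep fragments with length strictly below ``max_length_exclusive``."""
    for frag in fragments:
        if frag.length < max_length_exclusive:
            yield frag


@dataclass
class CountResult:
    """Single-sample count vector plus the tally of unassigned fragments."""

    counts: pd.Series  # indexed by window id, small resolution
    unassigned: int = 0
    assigned: int = field(init=False)

    def __post_init__(self) -> None:
        self.assigned = int(self.counts.sum())


def count_fragments(fragments: Iterable[FragmentRecord], windows: WindowSet) -> CountResult:
    """Assign each fragment to the small window containing its midpoint.

    The window test is half-open: midpoint m lands in [start, end) of a
    window on the same chromosome.  Fragments whose midpoint falls in no
    window are tallied as unassigned, so assigned + unassigned equals the
    input count.
    """
    if windows.resolution != "small":
        raise ValueError("count_fragments requires small-resolution windows")
    t = windows.table
    counts = np.zeros(len(t), dtype=np.int64)
    # per-chromosome sorted window starts for searchsorted lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in t.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub.index.to_numpy(),
        )
    unassigned = 0
    for frag in fragments:
        entry = by_chrom.get(frag.chrom)
        if entry is None:
            unassigned += 1
            continue
        starts, ends, idx = entry
        m = frag.midpoint
        j = int(np.searchsorted(starts, m, side="right")) - 1
        if j >= 0 and m < ends[j]:
            counts[idx[j]] += 1
        else:
            unassigned += 1
    return CountResult(pd.Series(counts, index=windows.ids), unassigned=unassigned)


def count_bam(
    path,
    windows: WindowSet,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    max_length_exclusive: int = MAX_FRAGMENT_LENGTH,
) -> CountResult:
    """Count short fragments from coordinate-sorted, indexed paired-end alignments.

    Properly paired, primary, non-duplicate first-mates with MAPQ >=
    ``mapq_min`` define fragments via template length; fragments are then
    filtered to insert size < ``max_length_exclusive`` and counted by
    midpoint exactly like BED input.
    """
    import pysam

    def fragment_stream() -> Iterator[FragmentRecord]:
        with pysam.AlignmentFile(str(path), "rb") as bam:
            if not bam.has_index():
                raise FileNotFoundError(f"missing BAM index for {path}")
            n_mapped = sum(bam.get_index_statistics()[i].mapped for i in range(bam.nreferences))
            if n_mapped == 0:
                warnings.warn(f"{path}: no mapped reads; counts are all zero")
            for read in bam.fetch():
                if (
                    not read.is_proper_pair
                    or not read.is_read1
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.is_unmapped
                    or read.mapping_quality < mapq_min
                ):
                    continue
                tlen = read.template_length
                if tlen == 0:
                    continue
                if tlen > 0:
                    start = read.reference_start
                    end = start + tlen
                else:
                    end = read.reference_end
                    start = end + tlen
                if end > start:
                    yield FragmentRecord(read.reference_name, start, end)

    return count_fragments(
        filter_short_fragments(fragment_stream(), max_length_exclusive), windows
    )


def counts_to_matrix(samples: Mapping[str, CountResult | pd.Series]) -> pd.DataFrame:
    """Stack per-sample count vectors into a samples x windows matrix."""
    rows = {}
    for name, res in samples.items():
        rows[name] = res.counts if isinstance(res, CountResult) else res
    mat = pd.DataFrame(rows).T
    mat.index.name = "sample"
    return mat
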