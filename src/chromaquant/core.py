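"""Shared value types for genome-anchored quantification.

All coordinates are 0-based, half-open, on both the internal types and the
BED-family file formats; 1-based formats (GTF, per-cytosine reports) are
converted at the I/O boundary.  Constructors validate their invariants and
raise rather than repair: silently "fixing" a malformed interval is how
off-by-one errors propagate through a pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Contig",
    "Genome",
    "Gene",
    "Interval",
    "FragmentSet",
    "CytosineReport",
    "WindowTrack",
    "BasewiseSignal",
    "MetaplotProfile",
    "QuintileGrouping",
    "InsertSizeStats",
]


@dataclass(frozen=True)
class Contig:
    """A named reference sequence; ``sequence`` is optional but, when
    present, must match the declared length."""

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.name!r}: length must be >= 1, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.name!r}: sequence length {len(self.sequence)} != declared {self.length}"
            )


@dataclass(frozen=True)
class Genome:
    """An ordered set of contigs with one designated mitochondrial contig.

    The nuclear/mitochondrial partition is load-bearing: ChIP enrichment is
    expressed relative to the mitochondrial background and the bisulfite
    nonconversion rate is estimated from the (unmethylated) mitochondrial
    genome, so the mitochondrial contig is named explicitly, never guessed.
    """

    contigs: tuple[Contig, ...]
    mito_name: str

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate contig names: {dupes}")
        if self.mito_name not in names:
            raise ValueError(
                f"mitochondrial contig {self.mito_name!r} not found in genome "
                f"(contigs: {names})"
            )

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contigs]

    @property
    def nuclear_names(self) -> list[str]:
        return [c.name for c in self.contigs if c.name != self.mito_name]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.contigs)

    def contig(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    def is_mito(self, name: str) -> bool:
        return name == self.mito_name

    def has_sequence(self) -> bool:
        return all(c.sequence is not None for c in self.contigs)


@dataclass(frozen=True)
class Gene:
    """An oriented gene interval carrying an expression value (RPKM).

    TSS/TTS follow the half-open convention: on the + strand the TSS is
    ``start``; on the − strand it is ``end - 1`` (the last base of the
    interval), and the TTS is symmetric.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    rpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.rpkm < 0:
            raise ValueError(f"gene {self.gene_id!r}: rpkm must be non-negative")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interval:
    """A plain genomic interval (methylated domain, DMR, window...)."""

    contig: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval on {self.contig}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


_FRAGMENT_COLUMNS = ("contig", "start", "end", "strand")


class FragmentSet:
    """Aligned fragments — the unit of ChIP/MNase coverage.

    Thin wrapper over a DataFrame with columns (contig, start, end, strand).
    Multiplicity is preserved: identical rows stay distinct until an explicit
    deduplication step. Insert size is ``end - start``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _FRAGMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns: {missing}")
        frame = frame.loc[:, list(_FRAGMENT_COLUMNS)].reset_index(drop=True)
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        bad = frame["start"] >= frame["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"fragment {i}: start {frame['start'].iat[i]} >= end {frame['end'].iat[i]}"
            )
        if (frame["start"] < 0).any():
            raise ValueError("fragment with negative start")
        bad_strand = ~frame["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError(
                f"fragment strand must be '+' or '-', got {frame.loc[bad_strand, 'strand'].iloc[0]!r}"
            )
        self.frame = frame

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, str]]) -> "FragmentSet":
        return cls(pd.DataFrame(records, columns=list(_FRAGMENT_COLUMNS)))

    def validate_against(self, genome: Genome) -> "FragmentSet":
        lengths = genome.lengths
        for contig, sub in self.frame.groupby("contig", sort=False):
            if contig not in lengths:
                raise ValueError(f"fragment on unknown contig {contig!r}")
            if int(sub["end"].max()) > lengths[contig]:
                raise ValueError(
                    f"fragment on {contig} extends past contig end ({lengths[contig]} bp)"
                )
        return self

    @property
    def lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[tuple[str, int, int, str]]:
        return iter(self.frame.itertuples(index=False, name=None))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return self.frame.equals(other.frame)


_REPORT_COLUMNS = ("contig", "pos", "strand", "m", "n")


class CytosineReport:
    """Per-cytosine bisulfite counts: unconverted reads ``m`` out of ``n``
    total, per (contig, pos, strand). Positions are 0-based internally."""

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing = [c for c in _REPORT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"cytosine report missing columns: {missing}")
        frame = frame.loc[:, list(_REPORT_COLUMNS)].reset_index(drop=True)
        for col in ("pos", "m", "n"):
            frame[col] = frame[col].astype(np.int64)
        if validate:
            if (frame["n"] < 0).any() or (frame["m"] < 0).any():
                raise ValueError("cytosine report: negative counts")
            if (frame["m"] > frame["n"]).any():
                raise ValueError("cytosine report: m > n at some site")
            if not frame["strand"].isin(["+", "-"]).all():
                raise ValueError("cytosine report: strand must be '+' or '-'")
            if frame.duplicated(subset=["contig", "pos", "strand"]).any():
                raise ValueError("cytosine report: duplicate (contig, pos, strand) rows")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def on_contig(self, contig: str) -> pd.DataFrame:
        return self.frame[self.frame["contig"] == contig]

    def in_region(self, region: Interval) -> pd.DataFrame:
        f = self.frame
        mask = (f["contig"] == region.contig) & (f["pos"] >= region.start) & (f["pos"] < region.end)
        return f[mask]


class WindowTrack:
    """Binned numeric signal over genomic windows.

    ``frame`` holds (contig, start, end, value) plus a ``partial`` flag for
    trailing windows shorter than the nominal width.  ``value_kind`` is one
    of raw_count / normalized_enrichment / weighted_methylation_percent.
    """

    VALUE_KINDS = ("raw_count", "normalized_enrichment", "weighted_methylation_percent")

    def __init__(self, frame: pd.DataFrame, value_kind: str):
        for col in ("contig", "start", "end", "value"):
            if col not in frame.columns:
                raise ValueError(f"window track missing column {col!r}")
        if value_kind not in self.VALUE_KINDS:
            raise ValueError(f"unknown value_kind {value_kind!r}")
        frame = frame.reset_index(drop=True)
        if (frame["start"] >= frame["end"]).any():
            raise ValueError("window track: start >= end")
        if value_kind == "normalized_enrichment" and (frame["value"] < 0).any():
            raise ValueError("normalized enrichment must be non-negative")
        if "partial" not in frame.columns:
            frame = frame.assign(partial=False)
        self.frame = frame
        self.value_kind = value_kind

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def on_contig(self, contig: str) -> pd.DataFrame:
        return self.frame[self.frame["contig"] == contig]


@dataclass
class BasewiseSignal:
    """Dense per-base signal, one float array per contig.

    This is the per-base specialisation of a window track (windows of width
    one); a dense array keeps metaplot extraction O(flank) per gene.
    """

    data: dict[str, np.ndarray]

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def genome_mean(self) -> float:
        n = sum(arr.size for arr in self.data.values())
        return self.total() / n if n else float("nan")

    def scaled_to_unit_mean(self) -> "BasewiseSignal":
        """Per-library normalization: rescale so the genome-wide mean is 1,
        making profiles comparable across libraries of different depth."""
        mean = self.genome_mean()
        if not mean > 0:
            raise ValueError("cannot scale a signal with non-positive genome mean")
        return BasewiseSignal({k: v / mean for k, v in self.data.items()})

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.data[contig]


@dataclass
class MetaplotProfile:
    """Average signal over regions aligned at a common anchor.

    ``bin_offsets`` are the left edges (bp) of the aggregation bins for
    TSS/TTS anchors.  For domain anchors they are bin indices: −20..−1 the
    upstream 50 bp flank bins, 0..19 the 5% body bins, 20..39 the downstream
    flank bins.
    """

    anchor: str
    bin_offsets: np.ndarray
    values: np.ndarray
    n_regions: int
    value_kind: str = "mean_signal"

    def __post_init__(self) -> None:
        self.bin_offsets = np.asarray(self.bin_offsets)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_offsets.shape != self.values.shape:
            raise ValueError("bin_offsets and values must have equal length")
        if len(self.bin_offsets) > 1 and not np.all(np.diff(self.bin_offsets) > 0):
            raise ValueError("bin_offsets must be strictly increasing")
        if self.n_regions < 1:
            raise ValueError("profile requires n_regions >= 1")

    def to_frame(self, group: str = "all") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": group,
                "offset": self.bin_offsets,
                "value": self.values,
                "n_regions": self.n_regions,
            }
        )


@dataclass
class QuintileGrouping:
    """Expression-ranked gene groups: group 1 = highest expression.

    ``boundaries[q]`` is the (max, min) RPKM of group q+1, mirroring how
    quintile ranges are conventionally reported.
    """

    assignment: dict[str, int]
    boundaries: list[tuple[float, float]]
    n_groups: int = 5

    def genes_in(self, q: int) -> list[str]:
        return [g for g, grp in self.assignment.items() if grp == q]

    def group_of(self, gene_id: str) -> int:
        return self.assignment[gene_id]


@dataclass
class InsertSizeStats:
    """Fragment length summary: mean, sample SD (n−1), and an integer-bin
    length histogram."""

    n_fragments: int
    mean_bp: float
    sd_bp: float
    histogram: pd.Series

    def __post_init__(self) -> None:
        if self.n_fragments >= 1 and not (
            self.histogram.index.min() <= self.mean_bp <= self.histogram.index.max()
        ):
            raise ValueError("mean outside observed length range")
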