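"""Readers and writers for the standard formats the pipeline touches.

Conventions at the boundary:

* FASTA is read through :mod:`pyfaidx` (genome), written as plain 70-column
  records.
* BED6 / BEDPE / bedGraph are native 0-based half-open and pass through
  unchanged; BEDPE mate pairs are collapsed to one fragment spanning the
  outermost coordinates.
* GTF is 1-based inclusive and converted on read/write.
* The per-cytosine report is a TSV with header ``contig  pos  strand  m  n``
  where ``pos`` is 1-based in the file (mirroring per-cytosine caller
  outputs) and 0-based in memory.

Readers reject invariant violations with the offending line number; they
never silently repair.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .core import (
    CytosineReport,
    Contig,
    FragmentSet,
    Gene,
    Genome,
    Interval,
    BasewiseSignal,
    WindowTrack,
)

__all__ = [
    "read_genome",
    "write_genome",
    "read_genes",
    "write_genes",
    "read_expression",
    "read_fragments",
    "write_fragments",
    "read_fragments_sam",
    "read_track",
    "write_track",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_intervals",
    "write_intervals",
    "track_to_signal",
]


# ---------------------------------------------------------------------------
# genome


def read_genome(path: str | os.PathLike, mito_name: str) -> Genome:
    """Read a genome FASTA, retaining sequences, and flag ``mito_name`` as
    the mitochondrial contig."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    try:
        fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True,
                      duplicate_action="stop")
    except ValueError as exc:  # pyfaidx signals duplicate names this way
        raise ValueError(f"while indexing {path}: {exc}") from exc
    contigs = tuple(
        Contig(name=name, length=len(fasta[name]), sequence=str(fasta[name][:]))
        for name in fasta.keys()
    )
    names = [c.name for c in contigs]
    if mito_name not in names:
        raise ValueError(
            f"mitochondrial contig {mito_name!r} absent from {path} (contigs: {names})"
        )
    return Genome(contigs=contigs, mito_name=mito_name)


def write_genome(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    if not genome.has_sequence():
        raise ValueError("cannot write a genome without sequences")
    with open(path, "w") as fh:
        for c in genome.contigs:
            fh.write(f">{c.name}\n")
            seq = c.sequence or ""
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# genes


def read_expression(path: str | os.PathLike) -> dict[str, float]:
    """Read a gene_id → RPKM table (TSV with header containing ``gene_id``
    and ``rpkm``)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "rpkm"):
        if col not in df.columns:
            raise ValueError(f"expression table {path} missing column {col!r}")
    return dict(zip(df["gene_id"].astype(str), df["rpkm"].astype(float)))


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_genes_gtf(path: str | os.PathLike, feature: str = "gene") -> list[Gene]:
    """Parse the gene_id-attribute GTF2 dialect.

    A hand parser (rather than a database-backed GFF library) keeps read
    errors attributable to a line number, which the contract requires.
    When no ``gene`` feature lines exist, gene extents are the union of
    same-gene_id feature lines (exon/CDS-style files).
    """
    rows: dict[str, dict] = {}
    order: list[str] = []
    saw_gene_feature = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            contig, _source, feat, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if start0 >= end0:
                raise ValueError(f"{path}:{lineno}: start >= end after conversion")
            gene_id = _parse_gtf_attributes(attrs).get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if feat == feature:
                saw_gene_feature = True
            if gene_id not in rows:
                rows[gene_id] = {
                    "contig": contig, "strand": strand, "start": start0, "end": end0,
                    "from_gene_feature": feat == feature,
                }
                order.append(gene_id)
            else:
                r = rows[gene_id]
                if feat == feature and not r["from_gene_feature"]:
                    r.update(start=start0, end=end0, from_gene_feature=True)
                elif not r["from_gene_feature"]:
                    r["start"] = min(r["start"], start0)
                    r["end"] = max(r["end"], end0)
                if r["contig"] != contig or r["strand"] != strand:
                    raise ValueError(f"{path}:{lineno}: gene {gene_id!r} spans contigs or strands")
    del saw_gene_feature
    return [
        Gene(gene_id=g, contig=rows[g]["contig"], strand=rows[g]["strand"],
             start=rows[g]["start"], end=rows[g]["end"])
        for g in order
    ]


def _read_genes_table(path: str | os.PathLike) -> list[Gene]:
    """Tab-separated gene table with header gene_id/contig/strand/start/end
    and optional rpkm; coordinates already 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str, "strand": str})
    required = ["gene_id", "contig", "strand", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} missing columns: {missing}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            genes.append(
                Gene(
                    gene_id=row.gene_id,
                    contig=row.contig,
                    strand=row.strand,
                    start=int(row.start),
                    end=int(row.end),
                    rpkm=float(getattr(row, "rpkm", 0.0)),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: {exc}") from exc
    return genes


def read_genes(
    path: str | os.PathLike,
    expression: str | os.PathLike | dict[str, float] | None = None,
) -> list[Gene]:
    """Read genes from GTF (``.gtf``/``.gff``) or a TSV gene table, attaching
    RPKM from ``expression`` where given.  Genes with no expression entry get
    RPKM 0 — they land in the lowest expression group, consistent with silent
    or rarely expressed genes."""
    ext = os.path.splitext(str(path))[1].lower()
    genes = _read_genes_gtf(path) if ext in (".gtf", ".gff") else _read_genes_table(path)
    if expression is not None:
        table = expression if isinstance(expression, dict) else read_expression(expression)
        genes = [
            Gene(g.gene_id, g.contig, g.strand, g.start, g.end, float(table.get(g.gene_id, 0.0)))
            for g in genes
        ]
    return genes


def write_genes(genes: Iterable[Gene], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.contig, g.strand, g.start, g.end, g.rpkm) for g in genes],
        columns=["gene_id", "contig", "strand", "start", "end", "rpkm"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# fragments


def read_fragments(
    path: str | os.PathLike,
    genome: Genome | None = None,
    fmt: str | None = None,
) -> FragmentSet:
    """Read BED6 or BEDPE fragments.  Format is taken from the extension
    (``.bedpe`` vs anything else) unless ``fmt`` is given explicitly.
    Multiplicity is preserved; no implicit deduplication."""
    if fmt is None:
        fmt = "bedpe" if str(path).lower().endswith(".bedpe") else "bed"
    if fmt not in ("bed", "bedpe"):
        raise ValueError(f"unknown fragment format {fmt!r}")
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if fmt == "bed":
                    contig, start, end = f[0], int(f[1]), int(f[2])
                    strand = f[5] if len(f) > 5 else "+"
                else:
                    if f[0] != f[3]:
                        raise ValueError("mates on different contigs")
                    contig = f[0]
                    start = min(int(f[1]), int(f[4]))
                    end = max(int(f[2]), int(f[5]))
                    strand = f[8] if len(f) > 8 else "+"
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if strand not in ("+", "-"):
                strand = "+"
            rows.append((contig, start, end, strand))
    fs = FragmentSet.from_records(rows) if rows else FragmentSet(
        pd.DataFrame(columns=["contig", "start", "end", "strand"])
    )
    if genome is not None:
        fs.validate_against(genome)
    return fs


def write_fragments(fragments: FragmentSet, path: str | os.PathLike) -> None:
    """Write fragments as BED6 (name '.', score '.')."""
    df = fragments.frame
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "start": df["start"],
            "end": df["end"],
            "name": ".",
            "score": ".",
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_fragments_sam(path: str | os.PathLike, genome: Genome | None = None) -> FragmentSet:
    """Thin SAM/BAM adapter delegating to pysam.

    Proper pairs are collapsed to one fragment via the leftmost mate's
    template length; unpaired mapped reads become read-length fragments.
    """
    import pysam  # optional dependency, imported lazily

    rows: list[tuple[str, int, int, str]] = []
    with pysam.AlignmentFile(str(path)) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            strand = "-" if read.is_reverse else "+"
            if read.is_paired:
                if read.template_length <= 0:  # count each pair once, from the left mate
                    continue
                rows.append(
                    (read.reference_name, read.reference_start,
                     read.reference_start + read.template_length, strand)
                )
            else:
                rows.append(
                    (read.reference_name, read.reference_start, read.reference_end, strand)
                )
    fs = FragmentSet.from_records(rows) if rows else FragmentSet(
        pd.DataFrame(columns=["contig", "start", "end", "strand"])
    )
    if genome is not None:
        fs.validate_against(genome)
    return fs


# ---------------------------------------------------------------------------
# tracks


def write_track(track: WindowTrack, path: str | os.PathLike) -> None:
    """Write a window track as bedGraph (0-based half-open, >= 6 significant
    digits).  Windows must be sorted and non-overlapping within contigs."""
    df = track.frame
    for contig, sub in df.groupby("contig", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValueError(f"unsorted windows on {contig}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping windows on {contig}")
    with open(path, "w") as fh:
        for contig, start, end, value in zip(df["contig"], df["start"], df["end"], df["value"]):
            fh.write(f"{contig}\t{start}\t{end}\t{value:.6g}\n")


def read_track(path: str | os.PathLike, value_kind: str = "raw_count") -> WindowTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "value"],
        dtype={"contig": str},
    ) if os.path.getsize(path) else pd.DataFrame(columns=["contig", "start", "end", "value"])
    return WindowTrack(df, value_kind=value_kind)


def track_to_signal(track: WindowTrack, genome: Genome) -> BasewiseSignal:
    """Expand a window track into dense per-base signal (each base takes its
    window's value)."""
    data = {c.name: np.zeros(c.length) for c in genome.contigs}
    for contig, start, end, value in zip(
        track.frame["contig"], track.frame["start"], track.frame["end"], track.frame["value"]
    ):
        data[contig][start:end] = value
    return BasewiseSignal(data)


# ---------------------------------------------------------------------------
# cytosine reports


def read_cytosine_report(path: str | os.PathLike) -> CytosineReport:
    """Read a per-cytosine TSV (header contig/pos/strand/m/n, pos 1-based in
    the file) into a 0-based :class:`CytosineReport`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str, "strand": str})
    missing = [c for c in ("contig", "pos", "strand", "m", "n") if c not in df.columns]
    if missing:
        raise ValueError(f"cytosine report {path} missing columns: {missing}")
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["pos"] < 0).any():
        raise ValueError(f"cytosine report {path}: positions must be 1-based (found 0)")
    return CytosineReport(df)


def write_cytosine_report(
    report: CytosineReport, path: str | os.PathLike, header_lines: Iterable[str] = ()
) -> None:
    df = report.frame.copy()
    df["pos"] = df["pos"] + 1
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals


def read_intervals(path: str | os.PathLike, genome: Genome | None = None) -> list[Interval]:
    """Read BED3+ intervals (column 4, when present, becomes the label)."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                iv = Interval(f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else None)
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if genome is not None and iv.contig not in genome:
                raise ValueError(f"{path}:{lineno}: unknown contig {iv.contig!r}")
            out.append(iv)
    return out


def write_intervals(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            label = iv.label if iv.label is not None else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{label}\n")
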