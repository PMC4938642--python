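"""MNase-seq fragment statistics and nucleosome-edge profiles.

Mononucleosomal fragment 5' ends mark nucleosome edges, so the average
plus-strand 5'-end depth around TSSs traces nucleosome phasing: a trough
over the nucleosome-free region, a peak at the +1 nucleosome edge, and
decaying peaks at one nucleosome-repeat-length intervals into the body.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .chip import basewise_coverage
from .core import FragmentSet, Gene, Genome, InsertSizeStats, MetaplotProfile, QuintileGrouping
from .metaplot import _aggregate_rows, per_gene_matrix

__all__ = ["deduplicate", "insert_size_stats", "edge_profile"]


def deduplicate(fragments: FragmentSet) -> FragmentSet:
    """Collapse fragments identical in (contig, start, end) to one
    representative.

    Strand is excluded from the duplicate key: a fragment's two reads share
    outer coordinates, which is how duplicate marking on paired data works.
    Output order is deterministic (sorted by contig, start, end).
    """
    df = (
        fragments.frame.drop_duplicates(subset=["contig", "start", "end"], keep="first")
        .sort_values(["contig", "start", "end"], kind="stable")
        .reset_index(drop=True)
    )
    return FragmentSet(df)


def insert_size_stats(fragments: FragmentSet) -> InsertSizeStats:
    """Mean and sample SD (n−1 denominator) of fragment lengths, plus an
    integer-bin length histogram."""
    if len(fragments) < 2:
        raise ValueError("insert size statistics require >= 2 fragments")
    lengths = fragments.lengths
    hist = pd.Series(lengths).value_counts().sort_index()
    return InsertSizeStats(
        n_fragments=len(fragments),
        mean_bp=float(np.mean(lengths)),
        sd_bp=float(np.std(lengths, ddof=1)),
        histogram=hist,
    )


def edge_profile(
    fragments: FragmentSet,
    genes: list[Gene],
    genome: Genome,
    grouping: QuintileGrouping | None = None,
    flank_bp: int = 1000,
    bin_bp: int = 10,
    strand_handling: str = "match_gene",
    deduplicated: bool = True,
) -> MetaplotProfile | dict[int, MetaplotProfile]:
    """Nucleosome-edge metaplot from fragment 5'-end depth around TSSs.

    ``match_gene`` (default): + strand genes aggregate genome plus-strand 5'
    ends; − strand genes aggregate genome minus-strand 5' ends, mirrored by
    the metaplot orientation flip — so for every gene, peaks mark the
    gene-oriented left edge of nucleosomes.  ``plus_only`` uses plus-strand
    5' ends for all genes regardless of orientation (the literal
    plus-strand-reads reading; profile peaks for − genes then mark right
    edges).
    """
    if strand_handling not in ("match_gene", "plus_only"):
        raise ValueError(f"unknown strand_handling {strand_handling!r}")
    if not deduplicated:
        warnings.warn("edge_profile input not flagged as deduplicated; duplicate "
                      "fragments will inflate peaks")
    sig_plus = basewise_coverage(fragments, genome, mode="five_prime_end",
                                 strand_filter="plus_only")
    if strand_handling == "plus_only":
        offsets, mat = per_gene_matrix(sig_plus, genes, "tss", flank_bp, bin_bp)
    else:
        sig_minus = basewise_coverage(fragments, genome, mode="five_prime_end",
                                      strand_filter="minus_only")
        offsets = None
        rows = []
        for g in genes:
            sig = sig_plus if g.strand == "+" else sig_minus
            offsets, row = per_gene_matrix(sig, [g], "tss", flank_bp, bin_bp)
            rows.append(row[0])
        mat = np.vstack(rows)
    return _aggregate_rows(offsets, mat, genes, "tss", grouping, "five_prime_end_depth")
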