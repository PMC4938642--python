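"""Anchored aggregation: TSS/TTS metaplots, expression quintiles,
expression-ordered heatmaps, and percent-binned domain methylation profiles.

Two aggregation conventions coexist on purpose and must not be conflated:

* Gene-anchored metaplots average per-gene bin means with **equal weight per
  gene** (the convention of aggregate-profile tools), so a deeply covered
  gene cannot dominate the profile.
* Domain methylation metaplots **pool counts** across domains per bin and
  report the weighted methylation percent of the pooled counts, matching the
  weighted-methylation-level definition (coverage-weighted by construction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import (
    BasewiseSignal,
    CytosineReport,
    Gene,
    Interval,
    MetaplotProfile,
    QuintileGrouping,
)

__all__ = [
    "assign_quintiles",
    "gene_metaplot",
    "heatmap_matrix",
    "domain_metaplot",
    "per_gene_matrix",
]


def assign_quintiles(genes: list[Gene], n_groups: int = 5) -> QuintileGrouping:
    """Rank genes by RPKM (descending, ties broken by gene_id ascending) and
    split into ``n_groups`` contiguous groups of near-equal size, remainders
    going to the earliest (most expressed) groups.  Group 1 = highest
    expression; genes with RPKM 0 land in the last group."""
    if len(genes) < n_groups:
        raise ValueError(f"need >= {n_groups} genes to form {n_groups} groups, got {len(genes)}")
    ranked = sorted(genes, key=lambda g: (-g.rpkm, g.gene_id))
    n = len(ranked)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    assignment: dict[str, int] = {}
    boundaries: list[tuple[float, float]] = []
    i = 0
    for q, size in enumerate(sizes, start=1):
        chunk = ranked[i : i + size]
        for g in chunk:
            assignment[g.gene_id] = q
        boundaries.append((chunk[0].rpkm, chunk[-1].rpkm))
        i += size
    return QuintileGrouping(assignment=assignment, boundaries=boundaries, n_groups=n_groups)


def _bin_offsets(flank_bp: int, bin_bp: int) -> np.ndarray:
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    return np.arange(-flank_bp, flank_bp, bin_bp, dtype=np.int64)


def per_gene_matrix(
    signal: BasewiseSignal,
    genes: list[Gene],
    anchor: str = "tss",
    flank_bp: int = 1000,
    bin_bp: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """One row of per-bin means per gene, oriented so positive offsets point
    into the gene body at the TSS (− strand genes are mirrored).  Bases past
    a contig edge are undefined (NaN-excluded), so truncated genes contribute
    only their defined bases.

    Returns (bin_offsets, matrix of shape (n_genes, n_bins)).
    """
    if anchor not in ("tss", "tts"):
        raise ValueError(f"anchor must be 'tss' or 'tts', got {anchor!r}")
    if not genes:
        raise ValueError("empty gene list")
    offsets = _bin_offsets(flank_bp, bin_bp)
    n_bins = offsets.size
    mat = np.full((len(genes), n_bins), np.nan)
    for i, g in enumerate(genes):
        arr = signal[g.contig]
        a = g.tss if anchor == "tss" else g.tts
        window = np.full(2 * flank_bp, np.nan)
        if g.strand == "+":
            lo, hi = a - flank_bp, a + flank_bp
            src_lo, src_hi = max(lo, 0), min(hi, arr.size)
            if src_hi > src_lo:
                window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        else:
            # gene-oriented offset o maps to genome position a - o
            lo, hi = a - flank_bp + 1, a + flank_bp + 1
            src_lo, src_hi = max(lo, 0), min(hi, arr.size)
            if src_hi > src_lo:
                rev = np.full(2 * flank_bp, np.nan)
                rev[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
                window = rev[::-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
            mat[i] = np.nanmean(window.reshape(n_bins, bin_bp), axis=1)
    return offsets, mat


def _aggregate_rows(
    offsets: np.ndarray,
    mat: np.ndarray,
    genes: list[Gene],
    anchor: str,
    grouping: QuintileGrouping | None,
    value_kind: str,
) -> MetaplotProfile | dict[int, MetaplotProfile]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if grouping is None:
            return MetaplotProfile(
                anchor=anchor, bin_offsets=offsets,
                values=np.nanmean(mat, axis=0), n_regions=len(genes), value_kind=value_kind,
            )
        out: dict[int, MetaplotProfile] = {}
        for q in range(1, grouping.n_groups + 1):
            idx = [i for i, g in enumerate(genes) if grouping.group_of(g.gene_id) == q]
            if not idx:
                continue
            out[q] = MetaplotProfile(
                anchor=anchor, bin_offsets=offsets,
                values=np.nanmean(mat[idx], axis=0), n_regions=len(idx), value_kind=value_kind,
            )
        return out


def gene_metaplot(
    signal: BasewiseSignal,
    genes: list[Gene],
    anchor: str = "tss",
    flank_bp: int = 1000,
    bin_bp: int = 10,
    grouping: QuintileGrouping | None = None,
    value_kind: str = "mean_signal",
) -> MetaplotProfile | dict[int, MetaplotProfile]:
    """Average anchored profile: per-gene bin means, then an unweighted mean
    over genes.  With ``grouping``, one profile per expression group."""
    offsets, mat = per_gene_matrix(signal, genes, anchor, flank_bp, bin_bp)
    return _aggregate_rows(offsets, mat, genes, anchor, grouping, value_kind)


def heatmap_matrix(
    signal: BasewiseSignal,
    genes: list[Gene],
    anchor: str = "tss",
    flank_bp: int = 1000,
    bin_bp: int = 10,
    order_by: str = "rpkm_desc",
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Per-gene profile matrix with rows ordered by expression, highest
    first (ties by gene_id).  Column means equal the ungrouped metaplot.

    Returns (matrix, row gene_ids, bin_offsets).
    """
    if order_by != "rpkm_desc":
        raise ValueError(f"unknown ordering {order_by!r}")
    ordered = sorted(genes, key=lambda g: (-g.rpkm, g.gene_id))
    offsets, mat = per_gene_matrix(signal, ordered, anchor, flank_bp, bin_bp)
    return mat, [g.gene_id for g in ordered], offsets


def domain_metaplot(
    report: CytosineReport,
    domains: list[Interval],
    flank_bins: int = 20,
    flank_bin_bp: int = 50,
    body_bins: int = 20,
    min_coverage: int = 3,
) -> MetaplotProfile:
    """Weighted methylation profile over methylated domains.

    Each domain body is split into ``body_bins`` equal-length bins (5% of the
    domain each by default); each flank into ``flank_bins`` fixed 50 bp bins.
    Counts are pooled across all domains per bin and each bin reports the
    weighted methylation percent of the pooled counts.  Bin offsets are
    indices: −20..−1 upstream, 0..19 body, 20..39 downstream.
    """
    if not domains:
        raise ValueError("empty domain list")
    n_bins = 2 * flank_bins + body_bins
    pooled_m = np.zeros(n_bins, dtype=np.int64)
    pooled_n = np.zeros(n_bins, dtype=np.int64)
    n_used = 0
    for dom in domains:
        if dom.length < body_bins:
            warnings.warn(
                f"domain {dom.contig}:{dom.start}-{dom.end} shorter than {body_bins} bp; skipped"
            )
            continue
        n_used += 1
        sub = report.on_contig(dom.contig)
        sub = sub[sub["n"] >= min_coverage]
        pos = sub["pos"].to_numpy()
        m = sub["m"].to_numpy()
        n = sub["n"].to_numpy()
        flank_bp = flank_bins * flank_bin_bp

        up = (pos >= dom.start - flank_bp) & (pos < dom.start)
        if up.any():
            b = (pos[up] - (dom.start - flank_bp)) // flank_bin_bp
            np.add.at(pooled_m, b, m[up])
            np.add.at(pooled_n, b, n[up])

        body = (pos >= dom.start) & (pos < dom.end)
        if body.any():
            # equal-length bins via integer scaling; bin i covers
            # [start + i*L/B, start + (i+1)*L/B)
            b = (pos[body] - dom.start) * body_bins // dom.length
            np.add.at(pooled_m, flank_bins + b, m[body])
            np.add.at(pooled_n, flank_bins + b, n[body])

        down = (pos >= dom.end) & (pos < dom.end + flank_bp)
        if down.any():
            b = (pos[down] - dom.end) // flank_bin_bp
            np.add.at(pooled_m, flank_bins + body_bins + b, m[down])
            np.add.at(pooled_n, flank_bins + body_bins + b, n[down])

    if n_used == 0:
        raise ValueError("no domain long enough to profile")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(pooled_n > 0, 100.0 * pooled_m / pooled_n, np.nan)
    offsets = np.arange(-flank_bins, flank_bins + body_bins, dtype=np.int64)
    return MetaplotProfile(
        anchor="domain", bin_offsets=offsets, values=values,
        n_regions=n_used, value_kind="weighted_methylation_percent",
    )
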