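"""Windowed ChIP coverage and mitochondrial-median normalization.

ChIP of a nuclear protein should not pull down mitochondrial DNA, so the
mitochondrial genome measures the immunoprecipitation background.  Dividing
each nuclear window's fragment count by the median count over mitochondrial
windows turns raw coverage into enrichment-over-background: a control
library gives values near 1 genome-wide, and a genuinely chromatin-bound
protein shows up as a global shift above 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BasewiseSignal, FragmentSet, Genome, WindowTrack

__all__ = ["EnrichmentConfig", "genome_windows", "window_counts", "mito_normalize", "basewise_coverage"]


@dataclass
class EnrichmentConfig:
    """window_bp: tiling window width (1000 bp default, the resolution at
    which genome-wide enrichment is scored).  count_rule: ``overlap`` counts
    a fragment in every window it intersects by >= 1 bp (BEDtools-coverage
    semantics); ``start_in_window`` assigns it once, by its start, so window
    counts sum exactly to the fragment count."""

    window_bp: int = 1000
    count_rule: str = "overlap"

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if self.count_rule not in ("overlap", "start_in_window"):
            raise ValueError(f"unknown count_rule {self.count_rule!r}")


def genome_windows(genome: Genome, window_bp: int) -> pd.DataFrame:
    """Tile each contig from 0 in steps of ``window_bp``; the trailing
    partial window is kept and flagged."""
    rows = []
    for c in genome.contigs:
        starts = np.arange(0, c.length, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, c.length)
        for s, e in zip(starts, ends):
            rows.append((c.name, int(s), int(e), e - s < window_bp))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "partial"])


def window_counts(
    fragments: FragmentSet, genome: Genome, cfg: EnrichmentConfig | None = None
) -> WindowTrack:
    """Count fragments per tiling window (raw_count track)."""
    cfg = cfg or EnrichmentConfig()
    fragments.validate_against(genome)
    w = cfg.window_bp
    windows = genome_windows(genome, w)
    counts: dict[str, np.ndarray] = {
        c.name: np.zeros(-(-c.length // w), dtype=np.int64) for c in genome.contigs
    }
    for contig, sub in fragments.frame.groupby("contig", sort=False):
        arr = counts[contig]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        first = starts // w
        if cfg.count_rule == "start_in_window":
            np.add.at(arr, first, 1)
        else:
            last = (ends - 1) // w
            np.add.at(arr, first, 1)
            d = 1
            mask = first + d <= last
            while mask.any():
                np.add.at(arr, first[mask] + d, 1)
                d += 1
                mask = first + d <= last
    values = np.concatenate([counts[c.name] for c in genome.contigs]) if len(windows) else np.array([])
    frame = windows.assign(value=values)
    return WindowTrack(frame, value_kind="raw_count")


def mito_normalize(track: WindowTrack, genome: Genome) -> WindowTrack:
    """Divide every window count by the median mitochondrial window count.

    The mitochondrial median defines the unit of enrichment, so degenerate
    denominators are hard errors, never silently patched.  Mitochondrial
    windows are kept in the output (their median maps to 1.0). The median of
    an even number of windows is the midpoint of the two central values.
    """
    if track.value_kind != "raw_count":
        raise ValueError(f"mito_normalize expects raw_count input, got {track.value_kind}")
    mito = track.on_contig(genome.mito_name)
    if len(mito) == 0:
        raise ValueError(f"no windows on mitochondrial contig {genome.mito_name!r}")
    denom = float(np.median(mito["value"].to_numpy()))
    if denom == 0:
        raise ValueError(
            f"median coverage of mitochondrial contig {genome.mito_name!r} is zero; "
            "enrichment over background is undefined"
        )
    frame = track.frame.assign(value=track.frame["value"].to_numpy() / denom)
    return WindowTrack(frame, value_kind="normalized_enrichment")


def basewise_coverage(
    fragments: FragmentSet,
    genome: Genome,
    mode: str = "full_fragment",
    strand_filter: str = "both",
) -> BasewiseSignal:
    """Per-base fragment coverage.

    mode ``full_fragment`` increments every base covered by the fragment;
    ``five_prime_end`` increments only the strand-aware 5' terminal base
    (start for +, end−1 for −), the quantity that marks nucleosome edges in
    MNase data.  ``strand_filter`` restricts to plus_only / minus_only
    fragments before counting.
    """
    if mode not in ("full_fragment", "five_prime_end"):
        raise ValueError(f"unknown mode {mode!r}")
    if strand_filter not in ("both", "plus_only", "minus_only"):
        raise ValueError(f"unknown strand_filter {strand_filter!r}")
    fragments.validate_against(genome)
    data = {c.name: np.zeros(c.length) for c in genome.contigs}
    df = fragments.frame
    if strand_filter == "plus_only":
        df = df[df["strand"] == "+"]
    elif strand_filter == "minus_only":
        df = df[df["strand"] == "-"]
    for contig, sub in df.groupby("contig", sort=False):
        arr = data[contig]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if mode == "five_prime_end":
            five = np.where(sub["strand"].to_numpy() == "+", starts, ends - 1)
            np.add.at(arr, five, 1.0)
        else:
            # difference-array trick: O(fragments + genome) instead of O(total bp)
            np.add.at(arr, starts, 1.0)
            inbounds = ends < arr.size
            np.add.at(arr, ends[inbounds], -1.0)
            np.cumsum(arr, out=arr)
    return BasewiseSignal(data)
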