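"""Whole-genome bisulfite methylome analysis.

The caller treats bisulfite nonconversion as the null: at a truly
unmethylated cytosine the unconverted count ``m`` out of ``n`` reads is
Binomial(n, r), where the nonconversion rate r is estimated by pooling all
reads over the (fully unmethylated) mitochondrial genome.  Each sufficiently
covered site gets a one-sided binomial tail p-value, Benjamini–Hochberg
correction runs over exactly the tested sites, and a site is called
methylated when its q-value falls at or below alpha.

Strands are never collapsed: methylation here is not restricted to a
symmetric sequence context, so each (contig, pos, strand) site is its own
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CytosineReport, Genome, Interval

__all__ = [
    "MethylomeConfig",
    "estimate_nonconversion",
    "bh_adjust",
    "call_sites",
    "count_methylated",
    "weighted_level",
    "shared_site_distribution",
    "find_dmrs",
]


@dataclass
class MethylomeConfig:
    """min_coverage: minimum reads for a site to be analysed (3).
    alpha: BH q-value threshold for calling a site methylated (0.05).
    DMR scan: pooled-count 2x2 conditional (Fisher) test on sliding windows
    of ``dmr_window_bp`` every ``dmr_step_bp``; windows need ``dmr_min_sites``
    sites covered in both samples, must pass BH at ``dmr_alpha`` AND differ
    by >= ``dmr_min_diff`` percentage points, and significant windows closer
    than ``dmr_merge_gap_bp`` merge into one region."""

    min_coverage: int = 3
    alpha: float = 0.05
    dmr_window_bp: int = 1000
    dmr_step_bp: int = 100
    dmr_min_diff: float = 20.0
    dmr_alpha: float = 0.05
    dmr_merge_gap_bp: int = 500
    dmr_min_sites: int = 5

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.dmr_window_bp < self.dmr_step_bp:
            raise ValueError("dmr_window_bp must be >= dmr_step_bp")
        if self.dmr_window_bp % self.dmr_step_bp != 0:
            raise ValueError("dmr_window_bp must be a multiple of dmr_step_bp")


def estimate_nonconversion(report: CytosineReport, genome: Genome) -> float:
    """Pooled mitochondrial nonconversion rate: (sum m) / (sum n) over all
    mitochondrial sites.  Pooling weights each read equally, the maximum-
    likelihood estimate of a single shared error rate."""
    mito = report.on_contig(genome.mito_name)
    total_n = int(mito["n"].sum())
    if total_n == 0:
        raise ValueError(
            f"no covered mitochondrial sites on {genome.mito_name!r}; "
            "nonconversion rate cannot be estimated"
        )
    return float(mito["m"].sum() / total_n)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: sort p ascending, q(k) =
    min_{j>=k} p(j)*T/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    t = p.size
    if t == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * t / np.arange(1, t + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(t)
    q[order] = q_sorted
    return q


def call_sites(
    report: CytosineReport, nonconversion: float, cfg: MethylomeConfig | None = None
) -> pd.DataFrame:
    """Per-site methylation calls.

    Returns the report frame extended with ``p_value``, ``q_value`` and
    ``status`` in {methylated, unmethylated, insufficient_coverage}.  Sites
    with n < min_coverage are excluded from testing and from the BH family;
    their p/q are NaN.
    """
    cfg = cfg or MethylomeConfig()
    if not (0 <= nonconversion < 1):
        raise ValueError(f"nonconversion rate must be in [0, 1), got {nonconversion}")
    df = report.frame.copy()
    n = df["n"].to_numpy()
    m = df["m"].to_numpy()
    tested = n >= cfg.min_coverage
    p = np.full(len(df), np.nan)
    q = np.full(len(df), np.nan)
    # one-sided upper tail: P(X >= m) for X ~ Binomial(n, r)
    p[tested] = stats.binom.sf(m[tested] - 1, n[tested], nonconversion)
    q[tested] = bh_adjust(p[tested])
    status = np.where(tested, np.where(q <= cfg.alpha, "methylated", "unmethylated"),
                      "insufficient_coverage")
    df["p_value"] = p
    df["q_value"] = q
    df["status"] = status
    return df


def count_methylated(calls: pd.DataFrame) -> int:
    """Total number of sites called methylated."""
    if len(calls) == 0:
        return 0
    return int((calls["status"] == "methylated").sum())


def weighted_level(
    report: CytosineReport, region: Interval, min_coverage: int = 3
) -> float:
    """Weighted methylation percent of a region: 100 * (sum m)/(sum n) over
    sites with n >= min_coverage.  Returns NaN (never a silent 0) when the
    region has no qualifying site."""
    sub = report.in_region(region)
    sub = sub[sub["n"] >= min_coverage]
    total_n = int(sub["n"].sum())
    if total_n == 0:
        return float("nan")
    return 100.0 * float(sub["m"].sum()) / total_n


def shared_site_distribution(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, bin_width: float = 5.0
) -> pd.DataFrame:
    """Distribution of per-site methylation levels at sites methylated in
    both samples.

    For each sample, the per-site level m/n of every shared site is binned
    (default 5% bins over [0, 100]) and expressed as a percent of shared
    sites, so each sample's column sums to 100.  Returns a frame with
    bin_low, bin_high, percent_a, percent_b.
    """
    key = ["contig", "pos", "strand"]
    ma = calls_a[calls_a["status"] == "methylated"]
    mb = calls_b[calls_b["status"] == "methylated"]
    shared = ma.merge(mb, on=key, suffixes=("_a", "_b"))
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    out = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:]})
    if len(shared) == 0:
        warnings.warn("no shared methylated sites between the two samples")
        out["percent_a"] = 0.0
        out["percent_b"] = 0.0
        return out
    for tag in ("a", "b"):
        level = 100.0 * shared[f"m_{tag}"] / shared[f"n_{tag}"]
        counts, _ = np.histogram(level, bins=edges)
        # a level of exactly 100 belongs to the top bin (np.histogram closes it)
        out[f"percent_{tag}"] = 100.0 * counts / len(shared)
    return out


def _merge_windows(
    hits: pd.DataFrame, merge_gap_bp: int
) -> list[Interval]:
    """Merge significant windows (same contig and direction) whose gaps are
    <= merge_gap_bp into DMR intervals."""
    out: list[Interval] = []
    for (contig, direction), sub in hits.groupby(["contig", "direction"], sort=False):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s - cur_e <= merge_gap_bp:
                cur_e = max(cur_e, e)
            else:
                out.append(Interval(contig, int(cur_s), int(cur_e), direction))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append(Interval(contig, int(cur_s), int(cur_e), direction))
    out.sort(key=lambda iv: (iv.contig, iv.start))
    return out


def find_dmrs(
    report_a: CytosineReport,
    report_b: CytosineReport,
    genome: Genome,
    cfg: MethylomeConfig | None = None,
) -> list[Interval]:
    """Differentially methylated regions between two samples.

    Sliding windows (``dmr_window_bp`` wide, every ``dmr_step_bp``) pool
    counts per sample over sites covered >= min_coverage in *both* samples.
    Each window with enough sites gets a two-sided Fisher exact test on the
    2x2 table (m_a, n_a−m_a; m_b, n_b−m_b); BH runs over tested windows;
    windows significant at dmr_alpha with an absolute weighted-level
    difference >= dmr_min_diff are merged (gap <= dmr_merge_gap_bp) into
    intervals labelled ``gain_in_b`` / ``loss_in_b``.
    """
    cfg = cfg or MethylomeConfig()
    key = ["contig", "pos", "strand"]
    joint = report_a.frame.merge(report_b.frame, on=key, suffixes=("_a", "_b"))
    joint = joint[
        (joint["n_a"] >= cfg.min_coverage) & (joint["n_b"] >= cfg.min_coverage)
    ]
    if len(joint) == 0:
        return []

    step = cfg.dmr_step_bp
    k = cfg.dmr_window_bp // step
    win_rows = []
    for contig in genome.names:
        sub = joint[joint["contig"] == contig]
        if len(sub) == 0:
            continue
        length = genome.lengths[contig]
        n_steps = -(-length // step)
        bins = (sub["pos"].to_numpy() // step).astype(np.int64)
        per_step = np.zeros((n_steps, 5), dtype=np.int64)  # ma, na, mb, nb, sites
        cols = np.column_stack(
            [sub["m_a"], sub["n_a"], sub["m_b"], sub["n_b"], np.ones(len(sub), dtype=np.int64)]
        )
        np.add.at(per_step, bins, cols)
        # rolling sum of k step-bins = sliding window
        csum = np.vstack([np.zeros((1, 5), dtype=np.int64), np.cumsum(per_step, axis=0)])
        n_windows = max(n_steps - k + 1, 1) if length >= cfg.dmr_window_bp else 1
        for w in range(n_windows):
            hi = min(w + k, n_steps)
            ma, na, mb, nb, sites = (csum[hi] - csum[w]).tolist()
            if sites < cfg.dmr_min_sites or na == 0 or nb == 0:
                continue
            win_rows.append(
                (contig, w * step, min(w * step + cfg.dmr_window_bp, length), ma, na, mb, nb)
            )
    if not win_rows:
        return []
    windows = pd.DataFrame(
        win_rows, columns=["contig", "start", "end", "ma", "na", "mb", "nb"]
    )
    diff = 100.0 * (windows["mb"] / windows["nb"] - windows["ma"] / windows["na"])
    pvals = np.ones(len(windows))
    # Fisher only where the effect gate can possibly pass: the gate is
    # applied after testing either way, so this is purely a shortcut
    for i, row in enumerate(windows.itertuples(index=False)):
        if row.ma * row.nb == row.mb * row.na:
            pvals[i] = 1.0
            continue
        table = [[row.ma, row.na - row.ma], [row.mb, row.nb - row.mb]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    qvals = bh_adjust(pvals)
    sig = (qvals <= cfg.dmr_alpha) & (diff.abs() >= cfg.dmr_min_diff)
    hits = windows[sig].copy()
    if len(hits) == 0:
        return []
    hits["direction"] = np.where(diff[sig] > 0, "gain_in_b", "loss_in_b")
    return _merge_windows(hits, cfg.dmr_merge_gap_bp)
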