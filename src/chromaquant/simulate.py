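"""Seeded synthetic data with the statistical structure the analyses assume.

The generator emulates, at toy-genome scale, the features the downstream
quantification depends on: a multi-contig nuclear genome plus one fully
unmethylated mitochondrial contig; genes on both strands with log-normal
expression and a silent fraction; non-overlapping heterochromatic
"methylated domains" with elevated per-cytosine methylation frequency;
bisulfite counts with a small nonconversion rate; ChIP fragments with a
global nuclear enrichment factor and an expression-scaled promoter boost;
and mononucleosomal MNase fragments from phased arrays downstream of a
nucleosome-free region.

Every simulator is a pure function of (inputs, seed): identical seeds give
byte-identical outputs.  Each simulator draws from its own seed stream so
that, e.g., regenerating the ChIP library does not perturb the methylome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import Contig, CytosineReport, FragmentSet, Gene, Genome, Interval
from .metaplot import assign_quintiles

__all__ = ["SimConfig", "simulate_genome", "simulate_bisulfite", "simulate_chip", "simulate_mnase"]

# per-simulator seed streams (mixed with the base seed via SeedSequence)
_STREAM_GENOME = 1
_STREAM_BISULFITE = 2
_STREAM_CHIP = 3
_STREAM_MNASE = 4

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic genome and libraries.

    Defaults describe a ~1 Mb two-chromosome toy genome with a 20 kb
    mitochondrial contig, 200 genes, ten 5 kb heterochromatin domains
    methylated at 45% (background unmethylated), bisulfite nonconversion
    0.5% at 20x coverage, 3x global nuclear ChIP enrichment with a 2x
    promoter boost, and mononucleosome fragments of 140 +/- 23 bp phased
    every 200 bp downstream of a 150 bp nucleosome-free region.  Library
    sizes (500k fragments) match the per-bp fragment depth of real
    sequencing libraries scaled to the toy genome.
    """

    seed: int = 0
    n_nuclear_contigs: int = 2
    contig_length_bp: int = 500_000
    mito_length_bp: int = 20_000
    n_genes: int = 200
    gene_length_bp: int = 1500
    rpkm_lognormal_mu: float = 1.5
    rpkm_lognormal_sigma: float = 2.0
    rpkm_zero_fraction: float = 0.2
    n_domains: int = 10
    domain_length_bp: int = 5000
    domain_meth_freq: float = 0.45
    background_meth_freq: float = 0.0
    nonconversion_rate: float = 0.005
    bs_mean_coverage: float = 20.0
    chip_nuclear_enrichment: float = 3.0
    chip_promoter_boost: float = 2.0
    chip_promoter_window_bp: int = 500
    chip_n_fragments: int = 500_000
    chip_fragment_len_mean: float = 200.0
    chip_fragment_len_sd: float = 30.0
    mnase_nfr_width_bp: int = 150
    mnase_spacing_bp: int = 200
    mnase_jitter_sd_bp: float = 20.0
    mnase_fragment_len_mean: float = 140.0
    mnase_fragment_len_sd: float = 23.0
    mnase_n_fragments: int = 500_000

    def __post_init__(self) -> None:
        for name in ("rpkm_zero_fraction", "domain_meth_freq", "background_meth_freq",
                     "nonconversion_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_nuclear_contigs", "contig_length_bp", "mito_length_bp",
                     "gene_length_bp", "chip_promoter_window_bp", "mnase_spacing_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_domains", "chip_n_fragments", "mnase_n_fragments",
                     "mnase_nfr_width_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bs_mean_coverage <= 0:
            raise ValueError("bs_mean_coverage must be positive")
        if self.chip_nuclear_enrichment < 1 or self.chip_promoter_boost < 1:
            raise ValueError("chip enrichment factors must be >= 1")
        total_nuclear = self.n_nuclear_contigs * self.contig_length_bp
        needed = self.n_genes * self.gene_length_bp + self.n_domains * self.domain_length_bp
        if needed > total_nuclear:
            raise ValueError(
                f"genes + domains ({needed} bp) cannot fit in {total_nuclear} bp of nuclear genome"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(base_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), stream]))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    length: int,
    contig_names: list[str],
    contig_lengths: dict[str, int],
    occupied: dict[str, list[tuple[int, int]]],
    max_retries: int = 1000,
) -> list[tuple[str, int, int]]:
    """Place n intervals of the given length uniformly on the listed contigs
    without overlapping each other or anything already in ``occupied``
    (which is updated in place)."""
    weights = np.array([contig_lengths[c] for c in contig_names], dtype=float)
    weights /= weights.sum()
    placed: list[tuple[str, int, int]] = []
    for _ in range(n):
        for attempt in range(max_retries):
            contig = contig_names[rng.choice(len(contig_names), p=weights)]
            hi = contig_lengths[contig] - length
            if hi < 0:
                continue
            start = int(rng.integers(0, hi + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in occupied[contig]):
                occupied[contig].append((start, end))
                placed.append((contig, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place interval of {length} bp after {max_retries} retries; "
                "genome too crowded"
            )
    return placed


def simulate_genome(cfg: SimConfig, seed: int | None = None) -> tuple[Genome, list[Gene], list[Interval]]:
    """Generate (genome, genes, methylated domains).

    Genes are non-overlapping with random strands; RPKM is log-normal with
    ``rpkm_zero_fraction`` of genes set to exactly 0 (silent).  Domains are
    non-overlapping and disjoint from genes, on nuclear contigs only — the
    mitochondrial contig contains cytosines but belongs to no domain.
    """
    rng = _rng(seed if seed is not None else cfg.seed, _STREAM_GENOME)
    contigs = []
    for i in range(cfg.n_nuclear_contigs):
        contigs.append(Contig(f"chr{i + 1}", cfg.contig_length_bp,
                              _random_sequence(rng, cfg.contig_length_bp)))
    contigs.append(Contig("mito", cfg.mito_length_bp, _random_sequence(rng, cfg.mito_length_bp)))
    genome = Genome(contigs=tuple(contigs), mito_name="mito")

    nuclear = genome.nuclear_names
    lengths = genome.lengths
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in nuclear}

    gene_spans = _place_nonoverlapping(
        rng, cfg.n_genes, cfg.gene_length_bp, nuclear, lengths, occupied
    )
    strands = rng.integers(0, 2, size=cfg.n_genes)
    rpkm = rng.lognormal(cfg.rpkm_lognormal_mu, cfg.rpkm_lognormal_sigma, size=cfg.n_genes)
    rpkm[rng.random(cfg.n_genes) < cfg.rpkm_zero_fraction] = 0.0
    width = len(str(max(cfg.n_genes, 1)))
    genes = [
        Gene(
            gene_id=f"gene_{i + 1:0{width}d}",
            contig=contig, strand="+" if strands[i] == 0 else "-",
            start=start, end=end, rpkm=float(rpkm[i]),
        )
        for i, (contig, start, end) in enumerate(gene_spans)
    ]

    domain_spans = _place_nonoverlapping(
        rng, cfg.n_domains, cfg.domain_length_bp, nuclear, lengths, occupied
    )
    dwidth = len(str(max(cfg.n_domains, 1)))
    domains = [
        Interval(contig, start, end, label=f"domain_{i + 1:0{dwidth}d}")
        for i, (contig, start, end) in enumerate(domain_spans)
    ]
    return genome, genes, domains


def _cytosine_positions(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Cytosine positions on the plus strand (C) and minus strand (G)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype="S1")
    return np.flatnonzero(arr == b"C"), np.flatnonzero(arr == b"G")


def simulate_bisulfite(
    genome: Genome,
    domains: list[Interval],
    cfg: SimConfig,
    seed: int | None = None,
    domain_meth_freq: float | None = None,
) -> CytosineReport:
    """Per-cytosine bisulfite counts for every C (both strands) in the
    genome.

    Coverage n ~ Poisson(bs_mean_coverage).  The true methylation frequency
    f is ``domain_meth_freq`` inside a domain, ``background_meth_freq``
    outside, and exactly 0 on the mitochondrial contig; the observed
    unconverted count is m ~ Binomial(n, f + (1−f)·nonconversion), the
    nonconversion applying to the unmethylated fraction of molecules.
    ``domain_meth_freq`` may be overridden per call to simulate strains that
    differ only in domain methylation.
    """
    if not genome.has_sequence():
        raise ValueError("bisulfite simulation requires genome sequences")
    f_dom = cfg.domain_meth_freq if domain_meth_freq is None else domain_meth_freq
    rng = _rng(seed if seed is not None else cfg.seed, _STREAM_BISULFITE)
    eps = cfg.nonconversion_rate
    frames = []
    for c in genome.contigs:
        plus, minus = _cytosine_positions(c.sequence)
        pos = np.concatenate([plus, minus])
        strand = np.concatenate([np.full(plus.size, "+"), np.full(minus.size, "-")])
        order = np.argsort(pos, kind="stable")
        pos, strand = pos[order], strand[order]
        if genome.is_mito(c.name):
            f = np.zeros(pos.size)
        else:
            f = np.full(pos.size, cfg.background_meth_freq)
            for dom in domains:
                if dom.contig == c.name:
                    f[(pos >= dom.start) & (pos < dom.end)] = f_dom
        n = rng.poisson(cfg.bs_mean_coverage, size=pos.size)
        m = rng.binomial(n, f + (1.0 - f) * eps)
        frames.append(pd.DataFrame({"contig": c.name, "pos": pos, "strand": strand, "m": m, "n": n}))
    return CytosineReport(pd.concat(frames, ignore_index=True), validate=False)


def _weighted_starts(
    rng: np.random.Generator, weights: np.ndarray, count: int
) -> np.ndarray:
    """Sample ``count`` base positions with per-base sampling weights."""
    csum = np.cumsum(weights)
    total = csum[-1]
    u = rng.random(count) * total
    return np.searchsorted(csum, u, side="right")


def _truncated_lengths(
    rng: np.random.Generator, mean: float, sd: float, count: int, floor: int = 50
) -> np.ndarray:
    """Normal fragment lengths with a hard floor (no rejection loops)."""
    return np.maximum(np.rint(rng.normal(mean, sd, size=count)).astype(np.int64), floor)


def simulate_chip(
    genome: Genome,
    genes: list[Gene],
    cfg: SimConfig,
    tagged: bool,
    seed: int | None = None,
) -> FragmentSet:
    """ChIP fragments for a tagged strain or an untagged control.

    Fragment start positions are drawn with per-base weight 1 on the
    mitochondrial contig.  For the tagged strain, nuclear bases carry weight
    ``chip_nuclear_enrichment`` (global chromatin binding), further
    multiplied inside each gene's promoter window (``chip_promoter_window_bp``
    upstream of the TSS) by 1 + (chip_promoter_boost − 1)·(G + 1 − q)/G for
    expression group q of G — the full boost for the most expressed group,
    shrinking linearly toward baseline for silent genes.  The control is
    uniform (weight 1 everywhere).  Fragment length ~ Normal(mean, sd)
    floored at 50 bp; strand uniform.
    """
    rng = _rng(seed if seed is not None else cfg.seed,
               _STREAM_CHIP * 10 + (1 if tagged else 0))
    weights = {c.name: np.ones(c.length) for c in genome.contigs}
    if tagged:
        for name in genome.nuclear_names:
            weights[name] *= cfg.chip_nuclear_enrichment
        if genes:
            grouping = assign_quintiles(genes, n_groups=min(5, len(genes)))
            g_n = grouping.n_groups
            for g in genes:
                q = grouping.group_of(g.gene_id)
                factor = 1.0 + (cfg.chip_promoter_boost - 1.0) * (g_n + 1 - q) / g_n
                if g.strand == "+":
                    lo, hi = g.tss - cfg.chip_promoter_window_bp, g.tss
                else:
                    lo, hi = g.tss + 1, g.tss + 1 + cfg.chip_promoter_window_bp
                lo = max(lo, 0)
                hi = min(hi, genome.lengths[g.contig])
                if hi > lo:
                    weights[g.contig][lo:hi] *= factor
    totals = np.array([weights[c.name].sum() for c in genome.contigs])
    counts = rng.multinomial(cfg.chip_n_fragments, totals / totals.sum())
    frames = []
    for c, count in zip(genome.contigs, counts):
        if count == 0:
            continue
        starts = _weighted_starts(rng, weights[c.name], int(count))
        lens = _truncated_lengths(rng, cfg.chip_fragment_len_mean, cfg.chip_fragment_len_sd, int(count))
        starts = np.minimum(starts, np.maximum(c.length - lens, 0))
        ends = np.minimum(starts + lens, c.length)
        strand = np.where(rng.integers(0, 2, size=int(count)) == 0, "+", "-")
        frames.append(pd.DataFrame({"contig": c.name, "start": starts, "end": ends, "strand": strand}))
    if not frames:
        return FragmentSet(pd.DataFrame(columns=["contig", "start", "end", "strand"]))
    return FragmentSet(pd.concat(frames, ignore_index=True))


def simulate_mnase(
    genome: Genome,
    genes: list[Gene],
    cfg: SimConfig,
    seed: int | None = None,
) -> FragmentSet:
    """Mononucleosomal fragments from phased arrays.

    For each gene, nucleosome (gene-oriented) left edges sit at TSS +
    k·spacing for k = 0, 1, 2, ... within the gene body, and no placements
    occur within ``mnase_nfr_width_bp`` upstream of the TSS (the
    nucleosome-free region).  Each phased fragment's gene-oriented left edge
    is a nucleosome edge plus Normal(0, jitter) bp; lengths are Normal(mean,
    sd) floored at 50 bp; strands uniform.  Fragments not assigned to a gene
    are placed uniformly over intergenic space (excluding NFRs), emulating
    unphased nucleosomes elsewhere.
    """
    if cfg.mnase_spacing_bp < cfg.mnase_fragment_len_mean:
        raise ValueError(
            f"nucleosome spacing ({cfg.mnase_spacing_bp} bp) smaller than mean fragment "
            f"length ({cfg.mnase_fragment_len_mean} bp): overlapping nucleosomes requested"
        )
    rng = _rng(seed if seed is not None else cfg.seed, _STREAM_MNASE)
    lengths = genome.lengths
    # intergenic sampling mask: exclude gene bodies (phased arrays live there)
    # and NFR zones (depleted by construction)
    inter = {c.name: np.ones(c.length) for c in genome.contigs}
    gene_bp = 0
    for g in genes:
        inter[g.contig][g.start:g.end] = 0.0
        gene_bp += g.length
        if g.strand == "+":
            lo, hi = g.tss - cfg.mnase_nfr_width_bp, g.tss
        else:
            lo, hi = g.tss + 1, g.tss + 1 + cfg.mnase_nfr_width_bp
        inter[g.contig][max(lo, 0) : min(hi, lengths[g.contig])] = 0.0
    inter_bp = sum(float(v.sum()) for v in inter.values())

    n_total = cfg.mnase_n_fragments
    p_genic = gene_bp / (gene_bp + inter_bp) if (gene_bp + inter_bp) > 0 else 0.0
    n_genic = rng.binomial(n_total, p_genic) if genes else 0
    n_inter = n_total - n_genic

    rows: list[pd.DataFrame] = []
    if n_genic and genes:
        gene_weights = np.array([g.length for g in genes], dtype=float)
        per_gene = rng.multinomial(n_genic, gene_weights / gene_weights.sum())
        for g, count in zip(genes, per_gene):
            if count == 0:
                continue
            n_edges = max(1, -(-g.length // cfg.mnase_spacing_bp))  # k·spacing < length
            k = rng.integers(0, n_edges, size=int(count))
            # jitter is truncated toward zero when discretised so the modal
            # 5'-end base stays exactly on the phased edge
            jitter = (
                np.trunc(rng.normal(0.0, cfg.mnase_jitter_sd_bp, size=int(count))).astype(np.int64)
                if cfg.mnase_jitter_sd_bp > 0
                else np.zeros(int(count), dtype=np.int64)
            )
            flen = _truncated_lengths(
                rng, cfg.mnase_fragment_len_mean, cfg.mnase_fragment_len_sd, int(count)
            )
            if g.strand == "+":
                left = g.tss + k * cfg.mnase_spacing_bp + jitter
                start, end = left, left + flen
            else:
                # gene-oriented left edge p maps to genomic interval [p−len+1, p+1)
                p = g.tss - k * cfg.mnase_spacing_bp - jitter
                start, end = p - flen + 1, p + 1
            L = lengths[g.contig]
            start = np.clip(start, 0, None)
            end = np.clip(end, None, L)
            ok = start < end
            strand = np.where(rng.integers(0, 2, size=int(count)) == 0, "+", "-")
            rows.append(pd.DataFrame({
                "contig": g.contig, "start": start[ok], "end": end[ok], "strand": strand[ok],
            }))
    if n_inter:
        totals = np.array([inter[c.name].sum() for c in genome.contigs])
        if totals.sum() > 0:
            counts = rng.multinomial(n_inter, totals / totals.sum())
            for c, count in zip(genome.contigs, counts):
                if count == 0:
                    continue
                starts = _weighted_starts(rng, inter[c.name], int(count))
                flen = _truncated_lengths(
                    rng, cfg.mnase_fragment_len_mean, cfg.mnase_fragment_len_sd, int(count)
                )
                ends = np.minimum(starts + flen, c.length)
                strand = np.where(rng.integers(0, 2, size=int(count)) == 0, "+", "-")
                rows.append(pd.DataFrame({
                    "contig": c.name, "start": starts, "end": ends, "strand": strand,
                }))
    if not rows:
        return FragmentSet(pd.DataFrame(columns=["contig", "start", "end", "strand"]))
    return FragmentSet(pd.concat(rows, ignore_index=True))
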