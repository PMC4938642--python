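"""End-to-end orchestration: configuration, logging, manifests.

A run is a pure function of (config, seed, input files): every stage logs
the exact parameter values it used, every output file lands in the manifest
with a checksum, and rerunning the same config and seed reproduces the
manifest bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .chip import EnrichmentConfig, basewise_coverage, mito_normalize, window_counts
from .core import Genome, Interval
from .metaplot import assign_quintiles, domain_metaplot, gene_metaplot
from .methylome import (
    MethylomeConfig,
    call_sites,
    count_methylated,
    estimate_nonconversion,
    find_dmrs,
    shared_site_distribution,
    weighted_level,
)
from .mnase import deduplicate, edge_profile, insert_size_stats
from .simulate import SimConfig, simulate_bisulfite, simulate_chip, simulate_genome, simulate_mnase

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("chromaquant")

ALL_STAGES = ("simulate", "chip", "methylome", "mnase", "metaplot")


@dataclass
class PipelineConfig:
    """Paths and per-stage settings for a pipeline run.

    When the ``simulate`` stage runs, its outputs feed the other stages and
    the input paths may stay unset; otherwise each requested stage names the
    inputs it needs.  ``mutant_domain_meth_freq`` is the domain methylation
    frequency of the second ("mutant-like") simulated methylome used for
    strain-to-strain comparison.
    """

    outdir: str = "chromaquant_run"
    seed: int = 0
    mito_name: str = "mito"
    sim: SimConfig = field(default_factory=SimConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    methylome: MethylomeConfig = field(default_factory=MethylomeConfig)
    metaplot_flank_bp: int = 1000
    metaplot_bin_bp: int = 10
    mutant_domain_meth_freq: float = 0.55
    # external inputs (used when simulate is not among the stages)
    genome_fa: str | None = None
    genes_path: str | None = None
    expression_path: str | None = None
    domains_bed: str | None = None
    chip_tagged: str | None = None
    chip_control: str | None = None
    mnase_fragments: str | None = None
    bisulfite_report: str | None = None
    bisulfite_report_b: str | None = None

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        if "enrichment" in kwargs and isinstance(kwargs["enrichment"], dict):
            kwargs["enrichment"] = EnrichmentConfig(**kwargs["enrichment"])
        if "methylome" in kwargs and isinstance(kwargs["methylome"], dict):
            kwargs["methylome"] = MethylomeConfig(**kwargs["methylome"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_profile_tsv(path: Path, profiles, header_lines=()) -> None:
    """Long-format TSV: group, offset, value, n_regions."""
    if not isinstance(profiles, dict):
        profiles = {"all": profiles}
    frames = [p.to_frame(group=str(k)) for k, p in profiles.items()]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False, float_format="%.6g")


class _MissingInput(ValueError):
    pass


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | list[str] = ALL_STAGES) -> dict:
    """Run the requested stages in dependency order and return the manifest.

    Stage failure aborts dependents but not independent stages; the manifest
    records per-stage status, every output file with its sha256, the config
    snapshot, the seed, and the package version.
    """
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r} (choose from {ALL_STAGES})")
    stages = [s for s in ALL_STAGES if s in stages]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    cfg_sim = dataclasses.replace(config.sim, seed=seed)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": config.to_dict(),
        "outputs": {},
        "status": {},
    }
    outputs: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = path
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # lazily resolved shared inputs -------------------------------------
    state: dict = {}

    def need(name: str, path_attr: str, loader):
        if name in state:
            return state[name]
        path = getattr(config, path_attr)
        if path is None:
            raise _MissingInput(
                f"stage requires {name!r} but no {path_attr!r} was configured and the "
                "simulate stage did not run"
            )
        state[name] = loader(path)
        return state[name]

    def get_genome() -> Genome:
        return need("genome", "genome_fa", lambda p: cio.read_genome(p, config.mito_name))

    def get_genes():
        return need("genes", "genes_path", lambda p: cio.read_genes(p, config.expression_path))

    def get_domains():
        return need("domains", "domains_bed", lambda p: cio.read_intervals(p, state.get("genome")))

    failed: set[str] = set()

    # ---------------------------------------------------------------- simulate
    if "simulate" in stages:
        log.info("simulate: seed=%d genome=%d+%d bp, %d genes, %d domains",
                 seed, cfg_sim.n_nuclear_contigs * cfg_sim.contig_length_bp,
                 cfg_sim.mito_length_bp, cfg_sim.n_genes, cfg_sim.n_domains)
        genome, genes, domains = simulate_genome(cfg_sim)
        state.update(genome=genome, genes=genes, domains=domains)
        cio.write_genome(genome, outdir / "genome.fa")
        emit("genome_fa", outdir / "genome.fa")
        cio.write_genes(genes, outdir / "genes.tsv")
        emit("genes_tsv", outdir / "genes.tsv")
        cio.write_intervals(domains, outdir / "domains.bed")
        emit("domains_bed", outdir / "domains.bed")
        for tag, name in ((True, "chip_tagged"), (False, "chip_control")):
            fs = simulate_chip(genome, genes, cfg_sim, tagged=tag)
            state[name] = fs
            cio.write_fragments(fs, outdir / f"{name}.bed")
            emit(f"{name}_bed", outdir / f"{name}.bed")
        for key, stream_seed in (("mnase", seed), ("mnase_b", seed + 10_007)):
            fs = simulate_mnase(genome, genes, cfg_sim, seed=stream_seed)
            state[key] = fs
            cio.write_fragments(fs, outdir / f"{key}.bed")
            emit(f"{key}_bed", outdir / f"{key}.bed")
        report_a = simulate_bisulfite(genome, domains, cfg_sim)
        report_b = simulate_bisulfite(
            genome, domains, cfg_sim, seed=seed + 20_011,
            domain_meth_freq=config.mutant_domain_meth_freq,
        )
        state["bisulfite_a"] = report_a
        state["bisulfite_b"] = report_b
        cio.write_cytosine_report(report_a, outdir / "bisulfite.tsv",
                                  [f"simulated domain_meth_freq={cfg_sim.domain_meth_freq}"])
        emit("bisulfite_tsv", outdir / "bisulfite.tsv")
        cio.write_cytosine_report(report_b, outdir / "bisulfite_b.tsv",
                                  [f"simulated domain_meth_freq={config.mutant_domain_meth_freq}"])
        emit("bisulfite_b_tsv", outdir / "bisulfite_b.tsv")
        manifest["status"]["simulate"] = "ok"

    # ---------------------------------------------------------------- chip
    if "chip" in stages:
        try:
            genome = state.get("genome") or get_genome()
            pairs = []
            for key, attr in (("chip_tagged", "chip_tagged"), ("chip_control", "chip_control")):
                if key in state:
                    pairs.append((key, state[key]))
                elif getattr(config, attr):
                    pairs.append((key, cio.read_fragments(getattr(config, attr), genome)))
            if not pairs:
                raise _MissingInput("chip stage requires fragment input (chip_tagged/chip_control)")
            for key, fs in pairs:
                raw = window_counts(fs, genome, config.enrichment)
                norm = mito_normalize(raw, genome)
                mito_median = float(np.median(raw.on_contig(genome.mito_name)["value"]))
                log.info("chip[%s]: %d fragments, window=%d bp, %d windows, mito median=%g",
                         key, len(fs), config.enrichment.window_bp, len(raw), mito_median)
                cio.write_track(norm, outdir / f"{key}.normalized.bedgraph")
                emit(f"{key}_normalized", outdir / f"{key}.normalized.bedgraph")
                state[f"{key}_norm"] = norm
            manifest["status"]["chip"] = "ok"
        except _MissingInput as exc:
            manifest["status"]["chip"] = f"failed: {exc}"
            failed.add("chip")
            log.error("chip stage failed: %s", exc)

    # ---------------------------------------------------------------- methylome
    if "methylome" in stages:
        try:
            genome = state.get("genome") or get_genome()
            report_a = state.get("bisulfite_a") or need(
                "bisulfite_a", "bisulfite_report", cio.read_cytosine_report)
            mcfg = config.methylome
            rate_a = estimate_nonconversion(report_a, genome)
            calls_a = call_sites(report_a, rate_a, mcfg)
            log.info("methylome[a]: nonconversion=%.5f min_coverage=%d alpha=%g "
                     "methylated=%d", rate_a, mcfg.min_coverage, mcfg.alpha,
                     count_methylated(calls_a))
            summary = {
                "nonconversion_a": rate_a,
                "methylated_count_a": count_methylated(calls_a),
            }
            domains = None
            try:
                domains = state.get("domains") or get_domains()
            except _MissingInput:
                pass
            if domains:
                lvl = [weighted_level(report_a, d, mcfg.min_coverage) for d in domains]
                summary["mean_domain_level_a"] = float(np.nanmean(lvl))
            report_b = state.get("bisulfite_b")
            if report_b is None and config.bisulfite_report_b:
                report_b = cio.read_cytosine_report(config.bisulfite_report_b)
            if report_b is not None:
                rate_b = estimate_nonconversion(report_b, genome)
                calls_b = call_sites(report_b, rate_b, mcfg)
                summary["nonconversion_b"] = rate_b
                summary["methylated_count_b"] = count_methylated(calls_b)
                shared = shared_site_distribution(calls_a, calls_b)
                shared.to_csv(outdir / "shared_site_distribution.tsv", sep="\t",
                              index=False, float_format="%.6g")
                emit("shared_site_distribution", outdir / "shared_site_distribution.tsv")
                dmrs = find_dmrs(report_a, report_b, genome, mcfg)
                cio.write_intervals(dmrs, outdir / "dmrs.bed")
                emit("dmrs_bed", outdir / "dmrs.bed")
                summary["n_dmrs"] = len(dmrs)
                if domains:
                    lvl = [weighted_level(report_b, d, mcfg.min_coverage) for d in domains]
                    summary["mean_domain_level_b"] = float(np.nanmean(lvl))
            with open(outdir / "methylome_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            emit("methylome_summary", outdir / "methylome_summary.json")
            manifest["status"]["methylome"] = "ok"
        except _MissingInput as exc:
            manifest["status"]["methylome"] = f"failed: {exc}"
            failed.add("methylome")
            log.error("methylome stage failed: %s", exc)

    # ---------------------------------------------------------------- mnase
    if "mnase" in stages:
        try:
            genome = state.get("genome") or get_genome()
            genes = state.get("genes") or get_genes()
            frames = []
            for key in ("mnase", "mnase_b"):
                fs = state.get(key)
                if fs is None and key == "mnase" and config.mnase_fragments:
                    fs = cio.read_fragments(config.mnase_fragments, genome)
                if fs is None:
                    continue
                dedup = deduplicate(fs)
                for label, frag in ((f"{key}_raw", fs), (f"{key}_dedup", dedup)):
                    s = insert_size_stats(frag)
                    frames.append((label, s.n_fragments, s.mean_bp, s.sd_bp))
                grouping = assign_quintiles(genes) if len(genes) >= 5 else None
                profiles = edge_profile(dedup, genes, genome, grouping=grouping,
                                        flank_bp=config.metaplot_flank_bp,
                                        bin_bp=config.metaplot_bin_bp)
                _write_profile_tsv(outdir / f"{key}_edge_profile.tsv", profiles,
                                   [f"bin={config.metaplot_bin_bp} flank={config.metaplot_flank_bp}"])
                emit(f"{key}_edge_profile", outdir / f"{key}_edge_profile.tsv")
            if not frames:
                raise _MissingInput("mnase stage requires fragment input (mnase_fragments)")
            pd.DataFrame(frames, columns=["sample", "n_fragments", "mean_bp", "sd_bp"]).to_csv(
                outdir / "insert_size_stats.tsv", sep="\t", index=False, float_format="%.6g")
            emit("insert_size_stats", outdir / "insert_size_stats.tsv")
            manifest["status"]["mnase"] = "ok"
        except _MissingInput as exc:
            manifest["status"]["mnase"] = f"failed: {exc}"
            failed.add("mnase")
            log.error("mnase stage failed: %s", exc)

    # ---------------------------------------------------------------- metaplot
    if "metaplot" in stages:
        try:
            genome = state.get("genome") or get_genome()
            genes = state.get("genes") or get_genes()
            fs = state.get("chip_tagged")
            if fs is None and config.chip_tagged:
                fs = cio.read_fragments(config.chip_tagged, genome)
            if fs is None:
                raise _MissingInput("metaplot stage requires ChIP fragments (chip_tagged)")
            signal = basewise_coverage(fs, genome, mode="full_fragment").scaled_to_unit_mean()
            grouping = assign_quintiles(genes) if len(genes) >= 5 else None
            log.info("metaplot: flank=%d bin=%d quintiles=%s", config.metaplot_flank_bp,
                     config.metaplot_bin_bp, grouping is not None)
            for anchor in ("tss", "tts"):
                profiles = gene_metaplot(signal, genes, anchor=anchor,
                                         flank_bp=config.metaplot_flank_bp,
                                         bin_bp=config.metaplot_bin_bp, grouping=grouping)
                _write_profile_tsv(outdir / f"chip_{anchor}_metaplot.tsv", profiles,
                                   [f"anchor={anchor} signal=chip_tagged unit-mean normalized"])
                emit(f"chip_{anchor}_metaplot", outdir / f"chip_{anchor}_metaplot.tsv")
            domains = None
            try:
                domains = state.get("domains") or get_domains()
            except _MissingInput:
                pass
            report_a = state.get("bisulfite_a")
            if report_a is None and config.bisulfite_report:
                report_a = cio.read_cytosine_report(config.bisulfite_report)
            if domains and report_a is not None:
                prof = domain_metaplot(report_a, domains,
                                       min_coverage=config.methylome.min_coverage)
                _write_profile_tsv(outdir / "domain_metaplot.tsv", prof,
                                   ["20x50bp flanks, 20x5% body bins, weighted methylation %"])
                emit("domain_metaplot", outdir / "domain_metaplot.tsv")
            manifest["status"]["metaplot"] = "ok"
        except _MissingInput as exc:
            manifest["status"]["metaplot"] = f"failed: {exc}"
            failed.add("metaplot")
            log.error("metaplot stage failed: %s", exc)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
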