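"""Stage orchestration: simulate -> clash profile -> NDRs -> regions -> match.

A :class:`RunConfig` (flat key/value mapping, YAML on disk) drives the
full workflow deterministically; every output TSV carries a provenance
header (parameter echo, seed, package version) and the final report is
a Table-1-shaped effect-size summary per region class x NDR kind x
expression class.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .matching import (
    DEFAULT_THRESHOLD_GRID,
    ThresholdPair,
    classify_expression,
    matched_experiment,
    stratify,
)
from .nome import (
    complement_hndr,
    define_regions,
    detect_lndr,
    filter_coverage,
    read_annotation,
    read_chrom_sizes,
    read_methylation,
    write_ndr_bed,
)
from .simulate import (
    SimConfig,
    simulate_annotation,
    simulate_methylation,
    simulate_tpm,
    write_chrom_sizes,
    write_gtf,
    planted_lndr_intervals,
)
from .structures import build_idealized_nucleosome, build_idealized_probe, read_pdb
from .superimpose import ClashProfile, compute_clash_profile

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline"]

log = logging.getLogger("nucsteric")


class ConfigError(ValueError):
    """Invalid or unknown configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Validated flat configuration for :func:`run_pipeline`."""

    out_dir: str = "nucsteric_run"
    seed: int = 0
    # inputs; None -> synthesized from the seed
    nucleosome_pdb: str | None = None
    probe_pdb: str | None = None
    gch_tsv: str | None = None
    hcg_tsv: str | None = None
    annotation_gtf: str | None = None
    chrom_sizes: str | None = None
    tpm_tsv: str | None = None
    # parameters
    probe_bp_start: int = 4
    probe_bp_end: int = 15
    min_reads: int = 3
    window_bp: int = 200
    step_bp: int = 20
    alpha: float = 1.0e-5
    upstream: int = 2000
    downstream: int = 1000
    c_thres_grid: tuple = (5,)
    m_thres_grid: tuple = (0,)
    register: str = "genomic"
    match_step: int = 1
    n_replicates: int = 1
    n_genes: int = 16
    coupling: float = 0.8

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        cfg = cls(**mapping)
        if cfg.register not in ("genomic", "window"):
            raise ConfigError("register must be 'genomic' or 'window'")
        if cfg.alpha <= 0 or cfg.alpha >= 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if cfg.min_reads < 0 or cfg.window_bp <= 0 or cfg.step_bp <= 0:
            raise ConfigError("window/step/min_reads must be positive")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a flat key/value mapping")
        for key in ("c_thres_grid", "m_thres_grid"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls.from_mapping(raw)

    def thresholds(self) -> list[ThresholdPair]:
        return [
            ThresholdPair(c, m) for c in self.c_thres_grid for m in self.m_thres_grid
        ]

    def stage_plan(self) -> list[str]:
        plan = []
        if self.gch_tsv is None:
            plan.append("simulate")
        plan += ["clash-profile", "call-ndr", "regions", "match", "report"]
        return plan


def _provenance(cfg: RunConfig) -> list[str]:
    echo = ", ".join(
        f"{f.name}={getattr(cfg, f.name)!r}" for f in dataclasses.fields(cfg)
    )
    return [f"nucsteric {__version__}", f"seed={cfg.seed}", echo]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        for line in _provenance(cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig, dry_run: bool = False) -> pd.DataFrame:
    """Execute all stages in dependency order; returns the effect report.

    With no experimental inputs configured, structures and methylation
    tables are synthesized from the seed, so a bare config is a full
    self-contained run.  Partial outputs are removed on failure.
    """
    if dry_run:
        for stage in cfg.stage_plan():
            log.info("plan: %s", stage)
        return pd.DataFrame()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_stages(cfg, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2fs", stage, time.perf_counter() - self.t0)

    return _T()


def _run_stages(cfg: RunConfig, out: Path, written: list[Path]) -> pd.DataFrame:
    for name in ("nucleosome_pdb", "probe_pdb", "gch_tsv", "hcg_tsv",
                 "annotation_gtf", "chrom_sizes", "tpm_tsv"):
        val = getattr(cfg, name)
        if val is not None and not Path(val).exists():
            raise DataError(f"input {name} not found: {val}")

    # --- structures & clash profile ---
    with _timed("clash-profile"):
        if cfg.nucleosome_pdb:
            nuc = read_pdb(cfg.nucleosome_pdb)
        else:
            nuc = build_idealized_nucleosome(seed=cfg.seed)
        if cfg.probe_pdb:
            probe = read_pdb(cfg.probe_pdb)
        else:
            probe = build_idealized_probe(seed=cfg.seed)
        profile = compute_clash_profile(
            nuc, probe, probe_bp_range=(cfg.probe_bp_start, cfg.probe_bp_end)
        )
        ppath = out / "clash_profile.tsv"
        profile.to_tsv(ppath, header_lines=_provenance(cfg))
        written.append(ppath)

    # --- inputs: simulate or load ---
    if cfg.gch_tsv is None:
        with _timed("simulate"):
            sim_cfg = SimConfig(seed=cfg.seed, n_genes=cfg.n_genes, coupling=cfg.coupling)
            genes, sizes = simulate_annotation(sim_cfg)
            tpm = simulate_tpm(sim_cfg, genes)
            sim = simulate_methylation(sim_cfg, genes, sizes, tpm, profile=profile)
            gch, hcg = sim["gch"], sim["hcg"]
            write_gtf(genes, out / "annotation.gtf")
            write_chrom_sizes(sizes, out / "chrom.sizes")
            for key in ("gch", "hcg"):
                _write_tsv(sim[key].drop(columns=["n_unmeth", "level"]),
                           out / f"{key}.tsv", cfg)
            _write_tsv(tpm, out / "tpm.tsv", cfg)
            _write_tsv(planted_lndr_intervals(sim_cfg, genes, tpm),
                       out / "truth_planted_lndrs.tsv", cfg)
            written += [out / "annotation.gtf", out / "chrom.sizes",
                        out / "gch.tsv", out / "hcg.tsv", out / "tpm.tsv",
                        out / "truth_planted_lndrs.tsv"]
    else:
        with _timed("load-inputs"):
            try:
                gch = read_methylation(cfg.gch_tsv, context="GCH")
                hcg = read_methylation(cfg.hcg_tsv, context="HCG")
                genes = read_annotation(cfg.annotation_gtf)
                sizes = read_chrom_sizes(cfg.chrom_sizes)
                tpm = pd.read_csv(cfg.tpm_tsv, sep="\t", comment="#")
            except (ValueError, OSError) as exc:
                raise DataError(str(exc)) from exc

    # --- NDR calling ---
    with _timed("call-ndr"):
        gch_f = filter_coverage(gch, cfg.min_reads)
        hcg_f = filter_coverage(hcg, cfg.min_reads)
        lndrs, qc = detect_lndr(
            gch_f, sizes, window_bp=cfg.window_bp, step_bp=cfg.step_bp, alpha=cfg.alpha
        )
        hndrs = complement_hndr(lndrs, sizes)
        ndrs = pd.concat([lndrs, hndrs], ignore_index=True)
        write_ndr_bed(ndrs, out / "ndrs.bed")
        written.append(out / "ndrs.bed")
        log.info("NDR QC: %s", qc)

    # --- regions ---
    with _timed("regions"):
        regions = define_regions(
            genes, sizes, upstream=cfg.upstream, downstream=cfg.downstream
        )
        _write_tsv(regions, out / "regions.tsv", cfg)
        written.append(out / "regions.tsv")

    # --- matching ---
    with _timed("match"):
        expr = classify_expression(tpm)
        matches = matched_experiment(
            ndrs, regions, hcg_f, profile,
            thresholds=cfg.thresholds(),
            expression_class=expr,
            seed=cfg.seed,
            n_replicates=cfg.n_replicates,
            register=cfg.register,
            step=cfg.match_step,
        )
        _write_tsv(matches, out / "window_matches.tsv", cfg)
        written.append(out / "window_matches.tsv")

    # --- report ---
    with _timed("report"):
        report = stratify(matches, ncpg_bins=[("10-20", 10, 20)])
        _write_tsv(report, out / "effect_report.tsv", cfg)
    return report
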