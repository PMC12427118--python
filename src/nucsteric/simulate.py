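"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the four experimental inputs — NOMe-style GCH and
HCG methylation tables, a toy gene annotation, and a gene-level TPM
table — on a single synthetic chromosome:

* expressed genes carry a planted nucleosome-depleted region (elevated
  GCH methylation) spanning -200..+100 bp around the TSS, over a uniform
  genome background, with sinusoidal nucleosome-phasing modulation of
  GCH levels downstream of the TSS;
* CpG (HCG) methylation outside the planted regions is optionally
  coupled to a steric-clash profile tiled along the chromosome (phase =
  position mod P): with probability ``coupling`` a CpG is methylated
  exactly when its position's clash is tolerated (c <= 5%), otherwise
  its state is a fair coin;
* read counts are binomial draws at Poisson coverage, the simplest model
  consistent with count-based chi-squared input.

Everything is deterministic per seed (numpy PCG64 Generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .superimpose import ClashProfile

__all__ = ["SimConfig", "simulate_annotation", "simulate_methylation",
           "simulate_tpm", "write_gtf", "write_chrom_sizes"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Densities and levels were fixed by an a-priori power analysis of the
    windowed chi-squared caller and of the 10-20-CpG match-score
    stratum; see the methods note.
    """

    seed: int = 0
    n_genes: int = 16
    chrom: str = "chrS"
    chrom_length: int | None = None          # derived from gene packing if None
    planted_lndr: tuple[int, int] = (-200, 100)   # oriented rel span, half-open
    gch_density: float = 0.05                # GpC sites per bp
    hcg_density: float = 0.11                # CpG sites per bp (island-like)
    coverage_mean: float = 10.0              # Poisson read depth
    background_gch_level: float = 20.0       # %
    lndr_gch_level: float = 65.0             # %
    hcg_meth_level: float = 85.0             # % level of a methylated CpG
    coupling: float = 0.8                    # P(CpG state follows accessibility)
    accessible_c_thres: float = 5.0          # % clash counted as accessible
    phasing_period: float = 190.0            # bp, nucleosome repeat downstream
    phasing_amplitude: float = 10.0          # % modulation of GCH level
    phasing_span: int = 1000                 # bp downstream of TSS
    exon_length: int = 300
    intron_length: int = 3500                # >= 3001 so region windows stay distinct
    intergenic_gap: int = 6000

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")
        if self.gch_density <= 0 or self.hcg_density <= 0:
            raise ValueError("site densities must be positive")
        for lvl in (self.background_gch_level, self.lndr_gch_level, self.hcg_meth_level):
            if not (0.0 <= lvl <= 100.0):
                raise ValueError("levels must lie in [0, 100]")
        if self.intron_length < 3001:
            raise ValueError("introns must be >= 3001 bp so region windows do not collide")

    @property
    def gene_footprint(self) -> int:
        return 3 * self.exon_length + 2 * self.intron_length


def simulate_annotation(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Toy annotation: non-overlapping 3-exon genes on both strands.

    Every gene has three exons, so all four region anchors (TSS, first
    intron start/end, second intron start) exist.  Returns the per-gene
    table (schema of :func:`nucsteric.nome.read_annotation`) and the
    chromosome-size map; TSS positions are ground truth by construction.
    """
    step = cfg.gene_footprint + cfg.intergenic_gap
    needed = cfg.n_genes * step + cfg.intergenic_gap
    length = cfg.chrom_length if cfg.chrom_length is not None else needed
    if length < needed:
        raise ValueError(
            f"chrom_length {length} cannot pack {cfg.n_genes} genes (need {needed})"
        )
    rows = []
    for g in range(cfg.n_genes):
        start = cfg.intergenic_gap + g * step
        end = start + cfg.gene_footprint
        strand = "+" if g % 2 == 0 else "-"
        exons = []
        cursor = start
        for _ in range(3):
            exons.append((cursor, cursor + cfg.exon_length))
            cursor += cfg.exon_length + cfg.intron_length
        rows.append(
            {
                "gene_id": f"gene{g:03d}",
                "chrom": cfg.chrom,
                "strand": strand,
                "start": start,
                "end": end,
                "exons": exons,
            }
        )
    genes = pd.DataFrame(rows)
    return genes, {cfg.chrom: int(length)}


def write_gtf(genes: pd.DataFrame, path: str | Path) -> None:
    """Write the toy annotation as deterministic GTF (gene + exon rows)."""
    lines = []
    for _, g in genes.iterrows():
        attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
        lines.append(
            f"{g.chrom}\tnucsteric_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for es, ee in g.exons:
            lines.append(
                f"{g.chrom}\tnucsteric_sim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{c}\t{s}" for c, s in sorted(sizes.items())) + "\n"
    )


def simulate_tpm(cfg: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Half of the genes expressed (log-normal TPM), half exactly zero."""
    rng = np.random.default_rng(cfg.seed + 1)
    expressed = np.arange(len(genes)) % 2 == 0
    tpm = np.where(expressed, np.round(rng.lognormal(2.0, 1.0, len(genes)), 3), 0.0)
    return pd.DataFrame(
        {"gene_id": genes["gene_id"], "tpm": tpm, "true_expressed": expressed}
    )


def planted_lndr_intervals(
    cfg: SimConfig, genes: pd.DataFrame, tpm: pd.DataFrame
) -> pd.DataFrame:
    """Ground-truth planted LNDR spans (expressed genes only), oriented."""
    expressed = set(tpm.loc[tpm["tpm"] > 0, "gene_id"])
    lo, hi = cfg.planted_lndr
    rows = []
    for _, g in genes.iterrows():
        if g["gene_id"] not in expressed:
            continue
        tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        if g["strand"] == "+":
            start, end = tss + lo, tss + hi
        else:
            start, end = tss - hi + 1, tss - lo + 1
        rows.append(
            {"chrom": g["chrom"], "start": int(start), "end": int(end),
             "gene_id": g["gene_id"]}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def _site_positions(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    return np.flatnonzero(rng.random(length) < density)


def _sample_reads(
    rng: np.random.Generator, levels: np.ndarray, coverage_mean: float
) -> tuple[np.ndarray, np.ndarray]:
    cov = rng.poisson(coverage_mean, size=len(levels))
    n_meth = rng.binomial(np.maximum(cov, 0), levels / 100.0)
    return n_meth, cov


def _site_table(
    chrom: str, pos: np.ndarray, strand: np.ndarray, context: str,
    n_meth: np.ndarray, cov: np.ndarray,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": pos.astype(np.int64),
            "end": pos.astype(np.int64) + 1,
            "strand": strand,
            "context": context,
            "n_meth": n_meth.astype(np.int64),
            "n_total": cov.astype(np.int64),
        }
    )
    df["n_unmeth"] = df["n_total"] - df["n_meth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["level"] = 100.0 * df["n_meth"] / df["n_total"]
    return df


def simulate_methylation(
    cfg: SimConfig,
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    tpm: pd.DataFrame,
    profile: ClashProfile | np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """GCH and HCG site tables plus ground-truth tables.

    Returns a dict with ``gch``, ``hcg`` (canonical site tables, reads
    included), ``planted_lndrs`` and ``hcg_truth`` (per-CpG planted
    state and accessibility indicator).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    length = int(chrom_sizes[cfg.chrom])
    planted = planted_lndr_intervals(cfg, genes, tpm)

    in_planted = np.zeros(length, dtype=bool)
    for s, e in zip(planted["start"], planted["end"]):
        in_planted[max(s, 0):min(e, length)] = True

    # --- GCH (accessibility) ---
    gch_pos = _site_positions(rng, length, cfg.gch_density)
    gch_level = np.full(len(gch_pos), cfg.background_gch_level)
    gch_level[in_planted[gch_pos]] = cfg.lndr_gch_level
    # nucleosome phasing downstream of expressed TSSs
    expressed = set(tpm.loc[tpm["tpm"] > 0, "gene_id"])
    for _, g in genes.iterrows():
        if g["gene_id"] not in expressed:
            continue
        tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        d = gch_pos - tss if g["strand"] == "+" else tss - gch_pos
        mask = (d > cfg.planted_lndr[1]) & (d <= cfg.phasing_span)
        gch_level[mask] += cfg.phasing_amplitude * np.cos(
            2.0 * np.pi * d[mask] / cfg.phasing_period
        )
    gch_level = np.clip(gch_level, 0.5, 99.5)
    gch_meth, gch_cov = _sample_reads(rng, gch_level, cfg.coverage_mean)
    gch_strand = np.where(rng.random(len(gch_pos)) < 0.5, "+", "-")

    # --- HCG (endogenous CpG methylation) ---
    hcg_pos = _site_positions(rng, length, cfg.hcg_density)
    coin = rng.random(len(hcg_pos)) < 0.5
    if profile is not None:
        clash = profile.clash_pct if isinstance(profile, ClashProfile) else np.asarray(profile, float)
        P = len(clash)
        accessible = clash[np.mod(hcg_pos, P)] <= cfg.accessible_c_thres
        follows = rng.random(len(hcg_pos)) < cfg.coupling
        state = np.where(follows, accessible, coin)
        # planted LNDRs are nucleosome-free: no steric constraint there
        state = np.where(in_planted[hcg_pos], coin, state)
    else:
        accessible = np.zeros(len(hcg_pos), dtype=bool)
        state = coin
    hcg_level = np.where(state, cfg.hcg_meth_level, 0.0)
    hcg_meth, hcg_cov = _sample_reads(rng, hcg_level, cfg.coverage_mean)
    hcg_strand = np.where(rng.random(len(hcg_pos)) < 0.5, "+", "-")

    truth = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": hcg_pos.astype(np.int64),
            "true_methylated": state,
            "accessible": accessible,
            "in_planted_lndr": in_planted[hcg_pos],
        }
    )
    return {
        "gch": _site_table(cfg.chrom, gch_pos, gch_strand, "GCH", gch_meth, gch_cov),
        "hcg": _site_table(cfg.chrom, hcg_pos, hcg_strand, "HCG", hcg_meth, hcg_cov),
        "planted_lndrs": planted,
        "hcg_truth": truth,
    }
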