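"""NOMe-seq methylation tables, LNDR/HNDR calling and region anatomy.

GpC (GCH context) methylation reports chromatin accessibility: exogenous
GpC methyltransferase can only mark nucleosome-free DNA.  Low
nucleosome-dense regions (LNDRs) are called by testing GCH methylated /
unmethylated read counts in 200-bp windows (20-bp steps) against the
genome background with a 2x2 chi-squared test; significant windows
(p < 1e-5 and window level above background) are merged into final
calls, and HNDRs are their per-chromosome set complement.  Endogenous
CpG (HCG context) methylation is then intersected with the four
anatomical region classes (-2000..+1000 bp around the TSS and the
first/second intron boundaries).

Coordinates are 0-based half-open (BED) throughout; methylation tables
are tab-separated with columns ``chrom start end strand context n_meth
n_total`` and sites carry ``level = 100 * n_meth / n_total``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .intervals import (
    as_intervals,
    complement_intervals,
    intersect_intervals,
    merge_intervals,
)

__all__ = [
    "METH_COLUMNS",
    "read_methylation",
    "write_methylation",
    "read_chrom_sizes",
    "filter_coverage",
    "detect_lndr",
    "complement_hndr",
    "read_annotation",
    "define_regions",
    "intersect",
    "aggregate_profile",
    "ndr_boundary_histogram",
    "write_ndr_bed",
]

METH_COLUMNS = ["chrom", "start", "end", "strand", "context", "n_meth", "n_total"]

ANCHOR_KINDS = ("promoter_tss", "intron1_start", "intron1_end", "intron2_start")


def _with_level(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["n_unmeth"] = df["n_total"] - df["n_meth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["level"] = 100.0 * df["n_meth"] / df["n_total"]
    return df


def read_methylation(
    path: str | Path,
    context: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a per-cytosine methylation TSV, sorted by (chrom, pos).

    ``column_map`` renames dialect columns onto the canonical schema
    (e.g. Bis-SNP-style headers).  ``context`` restricts to GCH or HCG;
    GCG sites never appear by construction (discarded upstream to avoid
    exogenous/endogenous cross-talk).
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse methylation table {path}: {exc}") from exc
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in METH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[(df["n_meth"] < 0) | (df["n_meth"] > df["n_total"])]
    if len(bad):
        raise ValueError(f"{path}: malformed counts at data row {bad[0] + 1}")
    if context is not None:
        df = df[df["context"] == context]
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return _with_level(df)


def write_methylation(df: pd.DataFrame, path: str | Path) -> None:
    df[METH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def filter_coverage(df: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Retain sites with read coverage strictly greater than ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    return df[df["n_total"] > min_reads].reset_index(drop=True)


def _chi2_2x2(a: np.ndarray, b: np.ndarray, c: float, d: float) -> np.ndarray:
    """Vectorized 2x2 chi-squared statistic (df=1, no Yates correction)."""
    a = a.astype(float)
    b = b.astype(float)
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(den > 0, num / den, 0.0)
    return stat


def detect_lndr(
    gch_sites: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window_bp: int = 200,
    step_bp: int = 20,
    alpha: float = 1e-5,
    min_window_reads: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Call LNDRs from coverage-filtered GCH sites.

    Each window's [methylated, unmethylated] counts are tested against
    the genome-wide background counts in a 2x2 chi-squared test (df=1);
    windows with ``p < alpha`` and window GpC level above the background
    level are significant, and overlapping or adjacent significant
    windows are merged into the final calls.  Windows with fewer than
    ``min_window_reads`` observations are skipped and QC-counted.

    Returns ``(calls, qc)`` where calls has columns chrom/start/end/kind/
    p_value/n_windows_merged and qc reports counts of windows examined,
    skipped and significant plus the background level.
    """
    bg_meth = float(gch_sites["n_meth"].sum())
    bg_unmeth = float((gch_sites["n_total"] - gch_sites["n_meth"]).sum())
    if bg_meth + bg_unmeth == 0:
        raise ValueError("no GCH observations to form a background")
    bg_level = 100.0 * bg_meth / (bg_meth + bg_unmeth)

    qc = {
        "n_windows": 0,
        "n_skipped_low_reads": 0,
        "n_significant": 0,
        "background_level": bg_level,
    }
    sig_rows = []
    for chrom, sub in gch_sites.groupby("chrom", sort=True):
        size = int(chrom_sizes[chrom])
        pos = sub["start"].to_numpy()
        meth = sub["n_meth"].to_numpy(float)
        tot = sub["n_total"].to_numpy(float)
        cm = np.concatenate([[0.0], np.cumsum(meth)])
        ct = np.concatenate([[0.0], np.cumsum(tot)])
        starts = np.arange(0, max(size - window_bp, 0) + 1, step_bp)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_bp, side="left")
        w_meth = cm[hi] - cm[lo]
        w_tot = ct[hi] - ct[lo]
        w_unmeth = w_tot - w_meth
        qc["n_windows"] += len(starts)
        enough = w_tot >= min_window_reads
        qc["n_skipped_low_reads"] += int(np.count_nonzero(~enough & (w_tot > 0)))
        stat = _chi2_2x2(w_meth, w_unmeth, bg_meth, bg_unmeth)
        pvals = chi2.sf(stat, df=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w_level = np.where(w_tot > 0, 100.0 * w_meth / w_tot, np.nan)
        sig = enough & (pvals < alpha) & (w_level > bg_level)
        for s, p in zip(starts[sig], pvals[sig]):
            sig_rows.append((chrom, int(s), int(min(s + window_bp, size)), float(p)))
    qc["n_significant"] = len(sig_rows)
    if not sig_rows:
        calls = pd.DataFrame(
            columns=["chrom", "start", "end", "kind", "p_value", "n_windows_merged"]
        )
        return calls, qc

    windows = pd.DataFrame(sig_rows, columns=["chrom", "start", "end", "p_value"])
    merged = merge_intervals(windows[["chrom", "start", "end"]])
    # min p-value among the member windows of each merged call
    pvs = []
    for _, row in merged.iterrows():
        member = windows[
            (windows["chrom"] == row["chrom"])
            & (windows["start"] < row["end"])
            & (windows["end"] > row["start"])
        ]
        pvs.append(float(member["p_value"].min()))
    calls = merged.rename(columns={"n_merged": "n_windows_merged"})
    calls["kind"] = "LNDR"
    calls["p_value"] = pvs
    return (
        calls[["chrom", "start", "end", "kind", "p_value", "n_windows_merged"]],
        qc,
    )


def complement_hndr(
    lndrs: pd.DataFrame, chrom_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """HNDRs: the per-chromosome complement of the (merged) LNDR calls."""
    comp = complement_intervals(
        lndrs[["chrom", "start", "end"]] if len(lndrs) else pd.DataFrame(columns=["chrom", "start", "end"]),
        chrom_sizes,
    )
    comp["kind"] = "HNDR"
    comp["p_value"] = np.nan
    comp["n_windows_merged"] = 0
    return comp


def write_ndr_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """BED6-style output: name = kind, score = p-value."""
    out = calls.copy()
    out["name"] = out["kind"]
    out["score"] = out["p_value"]
    out["strand"] = "."
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Gene anatomy
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Parse a GTF/GFF into a per-gene table with exon structure.

    Returns one row per gene: chrom, strand, gene_id, start, end (gene
    span, 0-based half-open) and ``exons`` — a list of (start, end)
    pairs sorted by genomic coordinate.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (e.start - 1, e.end)  # GTF is 1-based inclusive
            for e in db.children(gene, featuretype="exon")
        )
        rows.append(
            {
                "gene_id": gene.id,
                "chrom": gene.seqid,
                "strand": gene.strand,
                "start": gene.start - 1,
                "end": gene.end,
                "exons": exons,
            }
        )
    if not rows:
        raise ValueError(f"{path}: no gene features found")
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def _gene_anchors(gene: pd.Series) -> dict[str, int]:
    """0-based genomic positions of the four region anchors for one gene.

    Anchors are transcription-oriented: the 'start' of an intron is its
    transcriptionally first base.  Genes without introns emit only the
    promoter anchor; genes with a single intron lack intron2_start.
    """
    exons = gene["exons"]
    plus = gene["strand"] == "+"
    anchors: dict[str, int] = {}
    anchors["promoter_tss"] = gene["start"] if plus else gene["end"] - 1
    introns = [
        (exons[k][1], exons[k + 1][0]) for k in range(len(exons) - 1)
    ]  # genomic order
    if not introns:
        return anchors
    if plus:
        first, second = introns[0], (introns[1] if len(introns) > 1 else None)
        anchors["intron1_start"] = first[0]
        anchors["intron1_end"] = first[1] - 1
        if second:
            anchors["intron2_start"] = second[0]
    else:
        first = introns[-1]
        second = introns[-2] if len(introns) > 1 else None
        anchors["intron1_start"] = first[1] - 1
        anchors["intron1_end"] = first[0]
        if second:
            anchors["intron2_start"] = second[1] - 1
    return anchors


def define_regions(
    annotation: pd.DataFrame,
    chrom_sizes: Mapping[str, int] | None = None,
    upstream: int = 2000,
    downstream: int = 1000,
) -> pd.DataFrame:
    """Anchored windows of -upstream..+downstream bp around each anchor.

    Windows are transcription-oriented: for a + strand anchor ``a`` the
    window is ``[a - upstream, a + downstream + 1)``; for a - strand
    anchor it is mirrored.  Windows clipped at chromosome bounds are
    flagged (``clipped``) but still emitted.
    """
    rows = []
    for _, gene in annotation.iterrows():
        for kind, a in _gene_anchors(gene).items():
            if gene["strand"] == "+":
                start, end = a - upstream, a + downstream + 1
            else:
                start, end = a - downstream, a + upstream + 1
            clipped = False
            if chrom_sizes is not None:
                size = int(chrom_sizes[gene["chrom"]])
                cs, ce = max(start, 0), min(end, size)
                clipped = (cs, ce) != (start, end)
                start, end = cs, ce
            rows.append(
                {
                    "chrom": gene["chrom"],
                    "start": int(start),
                    "end": int(end),
                    "region_class": kind,
                    "gene_id": gene["gene_id"],
                    "strand": gene["strand"],
                    "anchor_pos": int(a),
                    "clipped": clipped,
                }
            )
    return as_intervals(pd.DataFrame(rows))


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Standard interval intersection (see :mod:`nucsteric.intervals`)."""
    return intersect_intervals(a, b)


def _oriented_rel(pos: np.ndarray, anchor: int, strand: str) -> np.ndarray:
    return pos - anchor if strand == "+" else anchor - pos


def aggregate_profile(
    sites: pd.DataFrame,
    regions: pd.DataFrame,
    value: str = "level",
    upstream: int = 2000,
    downstream: int = 1000,
) -> pd.DataFrame:
    """Mean per relative position of ``level`` or ``100_minus_level``.

    Sites are mapped to transcription-oriented positions -upstream..
    +downstream relative to each region's anchor; the output has one row
    per relative position with the mean value and the site count
    (positions with no sites are reported as NaN, not zero).
    """
    if value not in ("level", "100_minus_level"):
        raise ValueError("value must be 'level' or '100_minus_level'")
    span = upstream + downstream + 1
    sums = np.zeros(span)
    counts = np.zeros(span, dtype=int)
    for _, reg in regions.iterrows():
        sub = sites[
            (sites["chrom"] == reg["chrom"])
            & (sites["start"] >= reg["start"])
            & (sites["start"] < reg["end"])
        ]
        if not len(sub):
            continue
        rel = _oriented_rel(sub["start"].to_numpy(), reg["anchor_pos"], reg["strand"])
        idx = rel + upstream
        ok = (idx >= 0) & (idx < span)
        vals = sub["level"].to_numpy()[ok]
        if value == "100_minus_level":
            vals = 100.0 - vals
        np.add.at(sums, idx[ok], vals)
        np.add.at(counts, idx[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "rel_pos": np.arange(-upstream, downstream + 1),
            "mean_" + value: mean,
            "n_sites": counts,
        }
    )


def ndr_boundary_histogram(
    ndrs: pd.DataFrame,
    regions: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 1000,
) -> pd.DataFrame:
    """Counts of NDR starts/ends per transcription-oriented position.

    The 'start' of an NDR is its transcriptionally first boundary, so on
    the minus strand the genomic end maps to the start histogram.
    """
    span = upstream + downstream + 1
    start_counts = np.zeros(span, dtype=int)
    end_counts = np.zeros(span, dtype=int)
    for _, reg in regions.iterrows():
        sub = ndrs[
            (ndrs["chrom"] == reg["chrom"])
            & (ndrs["start"] < reg["end"])
            & (ndrs["end"] > reg["start"])
        ]
        for _, ndr in sub.iterrows():
            if reg["strand"] == "+":
                b_start, b_end = ndr["start"], ndr["end"] - 1
            else:
                b_start, b_end = ndr["end"] - 1, ndr["start"]
            for b, counts in ((b_start, start_counts), (b_end, end_counts)):
                rel = _oriented_rel(np.array([b]), reg["anchor_pos"], reg["strand"])[0]
                idx = rel + upstream
                if 0 <= idx < span:
                    counts[idx] += 1
    return pd.DataFrame(
        {
            "rel_pos": np.arange(-upstream, downstream + 1),
            "n_starts": start_counts,
            "n_ends": end_counts,
        }
    )
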