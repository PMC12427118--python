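"""Match-score between CpG methylation and the steric-clash profile.

A 136-bp window (the span with clashing information) slides at 1-bp
steps through every NDR-restricted region.  Each CpG in the window
contributes an agreement indicator

    M_i = 1  iff  (m_i > m_thres and c_i <= c_thres)
              or  (m_i <= m_thres and c_i > c_thres)

i.e. the CpG is methylated where the enzyme's steric clash is tolerated,
or unmethylated where it is not; the window's match-score is the mean of
M_i.  Experimental scores are compared against scores from randomly
shuffled methylation levels via the Wilcoxon rank-sum test and Cohen's d

    d = (m_e - m_r) / sqrt((s_e^2 + s_r^2) / 2)

stratified by the number of CpGs per window and the threshold pair
(c_thres, m_thres), labelled e.g. ``c5m0``.

Two registers relate genomic position to profile phase.  The default
``"genomic"`` register tiles the profile along the chromosome (phase =
position mod P), which is the register the synthetic generator plants
and therefore the one under which coupling is recoverable.  The
``"window"`` register scores every placement under its own assumed
nucleosome origin (window offset k -> profile position k+1); averaged
over uniformly placed windows it carries no recoverable signal on
translation-invariant data and is kept as an explicit negative control
and for register-free data exploration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .intervals import intersect_intervals
from .superimpose import ClashProfile

__all__ = [
    "ThresholdPair",
    "DEFAULT_THRESHOLD_GRID",
    "map_accessibility",
    "match_score",
    "sliding_match",
    "randomize_methylation",
    "cohens_d",
    "wilcoxon_test",
    "effect_size_class",
    "stratify",
    "classify_expression",
    "matched_experiment",
]


@dataclass(frozen=True)
class ThresholdPair:
    """Tolerated clash percentage and methylation-call threshold."""

    c_thres: float
    m_thres: float

    @property
    def label(self) -> str:
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)

        return f"c{fmt(self.c_thres)}m{fmt(self.m_thres)}"


DEFAULT_THRESHOLD_GRID = tuple(
    ThresholdPair(c, m) for c in (5, 10, 20, 50) for m in (0, 10, 20)
)


def map_accessibility(
    window_start: int,
    profile: ClashProfile | np.ndarray,
    positions: Sequence[int],
    levels: Sequence[float],
    orientation: str = "+",
) -> list[tuple[float, float]]:
    """Pair each CpG with the clash value at its window offset.

    A CpG at genomic offset k within the window receives the clash value
    at profile position k+1; with ``orientation="-"`` the offsets are
    mirrored (offset 0 -> position P).  CpGs outside the window are
    excluded, not an error.
    """
    clash = profile.clash_pct if isinstance(profile, ClashProfile) else np.asarray(profile, float)
    P = len(clash)
    pairs = []
    for pos, m in zip(positions, levels):
        k = pos - window_start
        if not 0 <= k < P:
            continue
        idx = k if orientation == "+" else P - 1 - k
        pairs.append((float(m), float(clash[idx])))
    return pairs


def _match_indicators(
    m: np.ndarray, c: np.ndarray, thr: ThresholdPair
) -> np.ndarray:
    methylated = m > thr.m_thres
    tolerated = c <= thr.c_thres
    return (methylated & tolerated) | (~methylated & ~tolerated)


def match_score(pairs: Sequence[tuple[float, float]], thr: ThresholdPair) -> float:
    """Mean agreement indicator over (m_i, c_i) pairs; boundary semantics:
    ``m_i == m_thres`` counts as unmethylated, ``c_i == c_thres`` as tolerated."""
    if len(pairs) == 0:
        raise ValueError("match score undefined for an empty window")
    arr = np.asarray(pairs, dtype=float)
    return float(np.mean(_match_indicators(arr[:, 0], arr[:, 1], thr)))


def _site_phase(pos: np.ndarray, P: int) -> np.ndarray:
    return np.mod(pos, P)


def sliding_match(
    ndrs: pd.DataFrame,
    regions: pd.DataFrame,
    cpg_sites: pd.DataFrame,
    profile: ClashProfile | np.ndarray,
    thr: ThresholdPair,
    step: int = 1,
    min_cpgs: int = 1,
    register: str = "genomic",
    data_kind: str = "experimental",
    replicate: int = 0,
) -> pd.DataFrame:
    """Match-scores for every window placement inside NDR-region overlaps.

    Windows have the profile's length, must fit entirely inside an
    NDR∩region segment and must contain at least ``min_cpgs`` CpGs.
    Output columns: region_class, ndr_kind, gene_id, chrom, window_start,
    n_cpgs, score, threshold, data_kind, replicate.
    """
    clash = profile.clash_pct if isinstance(profile, ClashProfile) else np.asarray(profile, float)
    P = len(clash)
    if register not in ("genomic", "window"):
        raise ValueError("register must be 'genomic' or 'window'")
    segments = intersect_intervals(
        ndrs[["chrom", "start", "end", "kind"]].rename(columns={"kind": "ndr_kind"}),
        regions[["chrom", "start", "end", "region_class", "gene_id", "strand"]],
    )
    rows: list[dict] = []
    if not len(segments):
        return _empty_matches()
    for chrom, sites in cpg_sites.groupby("chrom", sort=True):
        pos = sites["start"].to_numpy()
        lev = sites["level"].to_numpy(float)
        segs = segments[segments["chrom"] == chrom]
        if register == "genomic":
            agree = {
                thr.label: _match_indicators(lev, clash[_site_phase(pos, P)], thr)
            }
        for _, seg in segs.iterrows():
            seg_len = seg["end"] - seg["start"]
            if seg_len < P:
                continue
            w_starts = np.arange(seg["start"], seg["end"] - P + 1, step)
            lo = np.searchsorted(pos, w_starts, side="left")
            hi = np.searchsorted(pos, w_starts + P, side="left")
            n_cpgs = hi - lo
            keep = n_cpgs >= min_cpgs
            if register == "genomic":
                ind = agree[thr.label].astype(float)
                cind = np.concatenate([[0.0], np.cumsum(ind)])
                scores = np.where(
                    n_cpgs > 0, (cind[hi] - cind[lo]) / np.maximum(n_cpgs, 1), np.nan
                )
                for ws, n, sc in zip(w_starts[keep], n_cpgs[keep], scores[keep]):
                    rows.append(
                        _match_row(seg, chrom, int(ws), int(n), float(sc), thr,
                                   data_kind, replicate)
                    )
            else:
                for ws, l, h in zip(w_starts[keep], lo[keep], hi[keep]):
                    pairs = map_accessibility(
                        int(ws), clash, pos[l:h], lev[l:h], orientation="+"
                    )
                    rows.append(
                        _match_row(seg, chrom, int(ws), h - l,
                                   match_score(pairs, thr), thr, data_kind, replicate)
                    )
    return pd.DataFrame(rows) if rows else _empty_matches()


_MATCH_COLUMNS = [
    "region_class", "ndr_kind", "gene_id", "chrom", "window_start",
    "n_cpgs", "score", "threshold", "data_kind", "replicate",
]


def _empty_matches() -> pd.DataFrame:
    return pd.DataFrame(columns=_MATCH_COLUMNS)


def _match_row(seg, chrom, ws, n, score, thr, data_kind, replicate) -> dict:
    return {
        "region_class": seg["region_class"],
        "ndr_kind": seg["ndr_kind"],
        "gene_id": seg["gene_id"],
        "chrom": chrom,
        "window_start": ws,
        "n_cpgs": n,
        "score": score,
        "threshold": thr.label,
        "data_kind": data_kind,
        "replicate": replicate,
    }


def randomize_methylation(
    sites: pd.DataFrame,
    seed: int,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Permute methylation levels uniformly among CpG positions.

    Positions, contexts and coverage structure are untouched; the
    (n_meth, n_total, level) triple travels as a unit so the multiset of
    levels is preserved exactly.  ``groups`` names columns defining the
    shuffling scope (e.g. a region-class label); None shuffles across
    the whole table.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out = sites.reset_index(drop=True).copy()
    moved = ["n_meth", "level"]
    if groups:
        for _, idx in out.groupby(list(groups), sort=True).groups.items():
            idx = np.asarray(idx)
            perm = rng.permutation(len(idx))
            out.loc[idx, moved] = out.loc[idx[perm], moved].to_numpy()
    else:
        perm = rng.permutation(len(out))
        out[moved] = out.iloc[perm][moved].to_numpy()
    out["n_unmeth"] = out["n_total"] - out["n_meth"]
    return out


def cohens_d(exp_scores: Sequence[float], rand_scores: Sequence[float]) -> float:
    """Standardized mean difference with the averaged-variance pooling."""
    a = np.asarray(exp_scores, float)
    b = np.asarray(rand_scores, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Cohen's d needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0:
        raise ValueError("both group variances are zero: effect size undefined")
    return float((a.mean() - b.mean()) / denom)


def wilcoxon_test(exp_scores: Sequence[float], rand_scores: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for tiny groups,
    midrank normal approximation otherwise)."""
    a = np.asarray(exp_scores, float)
    b = np.asarray(rand_scores, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    return float(mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def effect_size_class(d: float) -> str:
    """Bin |d| at 0.2 / 0.5 / 0.8 (inclusive lower bounds)."""
    mag = abs(d)
    if mag >= 0.8:
        return "large"
    if mag >= 0.5:
        return "medium"
    if mag >= 0.2:
        return "small"
    return "negligible"


def classify_expression(tpm: pd.DataFrame) -> pd.Series:
    """TPM > 0 -> expressed, TPM <= 0 -> non_expressed (index: gene_id)."""
    if (tpm["tpm"] < 0).any():
        raise ValueError("TPM values must be >= 0")
    cls = np.where(tpm["tpm"] > 0, "expressed", "non_expressed")
    return pd.Series(cls, index=tpm["gene_id"].to_numpy(), name="expression_class")


def _ncpg_bins(max_single: int = 30, aggregate: tuple[int, int] = (10, 20)):
    bins: list[tuple[str, int, int]] = [
        (str(n), n, n) for n in range(1, max_single + 1)
    ]
    bins.append((f"{aggregate[0]}-{aggregate[1]}", aggregate[0], aggregate[1]))
    return bins


def stratify(
    matches: pd.DataFrame,
    ncpg_bins: Iterable[tuple[str, int, int]] | None = None,
    group_cols: Sequence[str] = ("region_class", "ndr_kind", "expression_class", "threshold"),
) -> pd.DataFrame:
    """Effect summaries per stratum x nCpG bin.

    ``matches`` must contain experimental and randomized rows
    (``data_kind``).  Strata with fewer than 2 values in either group
    are reported with NaN effect values rather than dropped.
    """
    bins = list(ncpg_bins) if ncpg_bins is not None else _ncpg_bins()
    group_cols = [c for c in group_cols if c in matches.columns]
    rows = []
    for key, sub in matches.groupby(group_cols, sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        for label, lo, hi in bins:
            inbin = sub[(sub["n_cpgs"] >= lo) & (sub["n_cpgs"] <= hi)]
            e = inbin.loc[inbin["data_kind"] == "experimental", "score"].to_numpy()
            r = inbin.loc[inbin["data_kind"] == "randomized", "score"].to_numpy()
            try:
                d = cohens_d(e, r)
                p = wilcoxon_test(e, r)
                size = effect_size_class(d)
            except ValueError:
                d, p, size = np.nan, np.nan, "NA"
            rows.append(
                dict(zip(group_cols, key))
                | {
                    "ncpg_bin": label,
                    "cohens_d": d,
                    "wilcoxon_p": p,
                    "n_exp": len(e),
                    "n_rand": len(r),
                    "size_class": size,
                }
            )
    return pd.DataFrame(rows)


def matched_experiment(
    ndrs: pd.DataFrame,
    regions: pd.DataFrame,
    cpg_sites: pd.DataFrame,
    profile: ClashProfile | np.ndarray,
    thresholds: Sequence[ThresholdPair] = (ThresholdPair(5, 0),),
    expression_class: pd.Series | None = None,
    seed: int = 0,
    n_replicates: int = 1,
    register: str = "genomic",
    step: int = 1,
) -> pd.DataFrame:
    """Experimental plus randomized match-scores for a threshold grid.

    The randomized arm permutes CpG methylation levels within each
    region-class x NDR-kind stratum (one permutation per replicate) and
    rescores the identical windows.  Expression classes, when supplied,
    are joined onto the output by gene id.
    """
    # assign each CpG its stratum for scoped shuffling
    site_cols = ["chrom", "start", "end", "level", "n_meth", "n_total"]
    seg = intersect_intervals(
        ndrs[["chrom", "start", "end", "kind"]].rename(columns={"kind": "ndr_kind"}),
        regions[["chrom", "start", "end", "region_class"]],
    )
    tagged = []
    sites_sorted = cpg_sites.sort_values(["chrom", "start"]).reset_index(drop=True)
    for (chrom, nk, rc), sub in (
        seg.groupby(["chrom", "ndr_kind", "region_class"], sort=True)
        if len(seg)
        else []
    ):
        ssub = sites_sorted[sites_sorted["chrom"] == chrom]
        pos = ssub["start"].to_numpy()
        mask = np.zeros(len(ssub), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            lo, hi = np.searchsorted(pos, [s, e], side="left")
            mask[lo:hi] = True
        picked = ssub[mask].copy()
        picked["stratum"] = f"{nk}|{rc}"
        tagged.append(picked)
    if tagged:
        tagged_df = (
            pd.concat(tagged)
            .drop_duplicates(subset=["chrom", "start"], keep="first")
            .sort_values(["chrom", "start"])
            .reset_index(drop=True)
        )
    else:
        tagged_df = sites_sorted.assign(stratum="all")

    frames = []
    for thr in thresholds:
        frames.append(
            sliding_match(
                ndrs, regions, tagged_df, profile, thr,
                step=step, register=register, data_kind="experimental",
            )
        )
        for rep in range(n_replicates):
            shuffled = randomize_methylation(
                tagged_df, seed=seed + 7919 * rep, groups=["stratum"]
            )
            frames.append(
                sliding_match(
                    ndrs, regions, shuffled, profile, thr,
                    step=step, register=register, data_kind="randomized",
                    replicate=rep,
                )
            )
    out = pd.concat(frames, ignore_index=True)
    if expression_class is not None and len(out):
        out["expression_class"] = (
            out["gene_id"].map(expression_class).fillna("unknown")
        )
    return out
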