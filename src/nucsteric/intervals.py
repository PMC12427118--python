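"""Genomic interval algebra on BED-semantics DataFrames.

Intervals are rows of a DataFrame with ``chrom`` (str), ``start`` and
``end`` (0-based half-open ints).  All operations sort internally and are
deterministic; ``intersect_intervals`` is contractually equal to the
quadratic all-pairs oracle.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "as_intervals",
    "merge_intervals",
    "complement_intervals",
    "intersect_intervals",
    "total_length",
]

_CORE = ["chrom", "start", "end"]


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate, coerce dtypes and sort by (chrom, start, end)."""
    missing = [c for c in _CORE if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns: {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["start"] >= out["end"]).any():
        raise ValueError("intervals must satisfy start < end")
    return out.sort_values(_CORE, kind="mergesort").reset_index(drop=True)


def total_length(df: pd.DataFrame) -> int:
    return int((df["end"] - df["start"]).sum())


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union of intervals; intervals closer than or touching ``gap`` merge.

    With the default ``gap=0``, adjacent intervals (end == next start)
    are merged and any 1-bp overlap merges a fortiori.
    """
    df = as_intervals(df)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e, n = starts[0], ends[0], 1
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, e)
                n += 1
            else:
                rows.append((chrom, cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        rows.append((chrom, cur_s, cur_e, n))
    return pd.DataFrame(rows, columns=_CORE + ["n_merged"])


def complement_intervals(
    df: pd.DataFrame, chrom_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome set complement within [0, chrom_size).

    Chromosomes present in ``chrom_sizes`` but absent from ``df`` yield a
    single full-length interval.  Input intervals must not exceed bounds.
    """
    if len(df):
        df = merge_intervals(df)
    rows = []
    covered = dict(tuple(df.groupby("chrom"))) if len(df) else {}
    for chrom in sorted(chrom_sizes):
        size = int(chrom_sizes[chrom])
        sub = covered.get(chrom)
        if sub is None:
            rows.append((chrom, 0, size))
            continue
        if (sub["end"] > size).any() or (sub["start"] < 0).any():
            raise ValueError(f"{chrom}: interval exceeds chromosome bounds")
        cursor = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > cursor:
                rows.append((chrom, cursor, int(s)))
            cursor = int(e)
        if cursor < size:
            rows.append((chrom, cursor, size))
    return pd.DataFrame(rows, columns=_CORE)


def intersect_intervals(
    a: pd.DataFrame, b: pd.DataFrame, suffixes: tuple[str, str] = ("_a", "_b")
) -> pd.DataFrame:
    """All pairwise overlaps between two interval sets.

    Returns one row per overlapping (a, b) pair with the intersection
    span in ``start``/``end``; non-core columns of both inputs are
    carried through (suffixed on collision).
    """
    if not len(a) or not len(b):
        return pd.DataFrame(columns=_CORE)
    a = as_intervals(a)
    b = as_intervals(b)
    extra_a = [c for c in a.columns if c not in _CORE]
    extra_b = [c for c in b.columns if c not in _CORE]
    rows = []
    for chrom, sub_a in a.groupby("chrom", sort=True):
        sub_b = b[b["chrom"] == chrom]
        if not len(sub_b):
            continue
        bs = sub_b["start"].to_numpy()
        be = sub_b["end"].to_numpy()
        # candidates have b.start < a.end (bs sorted); b.end checked per pair,
        # so overlapping b-intervals are handled correctly
        hi = np.searchsorted(bs, sub_a["end"].to_numpy(), side="left")
        for (_, ra), last in zip(sub_a.iterrows(), hi):
            for j in range(int(last)):
                if be[j] <= ra["start"]:
                    continue
                s = max(ra["start"], bs[j])
                e = min(ra["end"], be[j])
                if s < e:
                    row = {"chrom": chrom, "start": int(s), "end": int(e)}
                    rb = sub_b.iloc[j]
                    for c in extra_a:
                        key = c + suffixes[0] if c in extra_b else c
                        row[key] = ra[c]
                    for c in extra_b:
                        key = c + suffixes[1] if c in extra_a else c
                        row[key] = rb[c]
                    rows.append(row)
    if not rows:
        return pd.DataFrame(columns=_CORE)
    return pd.DataFrame(rows).sort_values(_CORE, kind="mergesort").reset_index(drop=True)
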