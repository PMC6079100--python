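"""Interval bookkeeping and association statistics for peak sets.

Coordinates are 0-based half-open throughout (BED convention).  Peak
"summits" default to the interval midpoint (floor division) when no
summit column is present.  Overlap significance between a tested peak
set and a bound region set is modelled as a hypergeometric draw from an
explicit region universe — the universe is a required argument, never
inferred.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .signatures import wilcoxon_rank_sum

__all__ = [
    "read_bed",
    "write_bed",
    "summits",
    "classify_summits",
    "overlap_enrichment_test",
    "peaks_near_tss",
    "stratify_fragments",
    "site_signal_compare",
    "pairwise_set_counts",
]

_BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(source) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame; rejects invalid coordinates."""
    table = pd.read_csv(
        source,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
    )
    if table.shape[1] < 3:
        raise ValueError("BED requires at least 3 columns")
    table = table.iloc[:, :6]
    table.columns = _BED6[: table.shape[1]]
    table["start"] = table["start"].astype(np.int64)
    table["end"] = table["end"].astype(np.int64)
    bad = (table["start"] < 0) | (table["start"] >= table["end"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(
            f"invalid interval at line {line}: start >= end or start < 0"
        )
    return table


def write_bed(intervals: pd.DataFrame, target) -> None:
    """Write the BED3/BED6 columns present in the frame, tab-separated."""
    cols = [c for c in _BED6 if c in intervals.columns]
    if not {"chrom", "start", "end"} <= set(cols):
        raise ValueError("intervals need chrom/start/end columns")
    intervals[cols].to_csv(target, sep="\t", header=False, index=False)


def summits(intervals: pd.DataFrame) -> np.ndarray:
    """Summit positions: the 'summit' column if present, else midpoints."""
    if "summit" in intervals.columns:
        return intervals["summit"].to_numpy(np.int64)
    return (
        (intervals["start"].to_numpy(np.int64)
         + intervals["end"].to_numpy(np.int64)) // 2
    )


def _trees(regions: pd.DataFrame) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, sub in regions.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"])
        )
    return trees


def _summit_in(trees: Mapping[str, IntervalTree],
               chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for i, (c, p) in enumerate(zip(chrom, pos)):
        tree = trees.get(c)
        if tree is not None and tree.overlaps_point(int(p)):
            hit[i] = True
    return hit


def classify_summits(
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    enhancers: pd.DataFrame,
) -> pd.Series:
    """Class per peak: 'promoter', 'enhancer' or 'neither'.

    Containment is half-open point-in-interval on the summit; a summit
    inside both region types is classed 'promoter' (precedence rule).
    """
    pos = summits(peaks)
    chrom = peaks["chrom"].to_numpy()
    in_prom = _summit_in(_trees(promoters), chrom, pos)
    in_enh = _summit_in(_trees(enhancers), chrom, pos)
    cls = np.where(in_prom, "promoter", np.where(in_enh, "enhancer", "neither"))
    return pd.Series(cls, index=peaks.index, name="class")


def overlap_enrichment_test(k: int, n: int, K: int, N: int) -> float:
    """Hypergeometric upper-tail overlap significance.

    ``k`` of ``n`` tested peaks fall in regions bound by the other
    factor, which covers ``K`` of the ``N`` universe regions; returns
    P(X >= k) with X ~ Hypergeom(N, K, n).
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError("inconsistent counts: need k <= min(n, K) and n, K <= N")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def peaks_near_tss(
    peaks: pd.DataFrame,
    tss: Mapping[str, Tuple[str, int]],
    window: int = 50_000,
) -> Dict[str, list]:
    """Assign peaks to genes whose TSS lies within ``window`` bp of the
    summit (inclusive, strand-agnostic absolute distance).

    ``tss`` maps gene -> (chrom, position).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pos = summits(peaks)
    chrom = peaks["chrom"].to_numpy()
    names = (
        peaks["name"].to_numpy()
        if "name" in peaks.columns
        else peaks.index.to_numpy()
    )
    out: Dict[str, list] = {}
    for gene, (g_chrom, g_pos) in tss.items():
        mask = (chrom == g_chrom) & (np.abs(pos - int(g_pos)) <= window)
        if mask.any():
            out[gene] = list(names[mask])
    return out


def stratify_fragments(
    fragments: pd.DataFrame, cutoff: int = 146
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition fragments into sub-nucleosomal (< cutoff bp) and
    nucleosomal (>= cutoff bp) sets by insert size (end - start)."""
    size = fragments["end"].to_numpy(np.int64) - fragments["start"].to_numpy(
        np.int64
    )
    if (size <= 0).any():
        raise ValueError("fragment insert sizes must be positive")
    sub = fragments[size < cutoff]
    nuc = fragments[size >= cutoff]
    return sub, nuc


def site_signal_compare(
    signal_a: Sequence[float],
    signal_b: Sequence[float],
    bound: Sequence[bool],
) -> Dict[str, object]:
    """Compare per-site signal changes between bound and unbound sites.

    Deltas are ``B - A`` per site; a two-sided rank-sum test asks whether
    bound sites change differently from unbound sites.
    """
    a = np.asarray(signal_a, float)
    b = np.asarray(signal_b, float)
    bound = np.asarray(bound, bool)
    if not (len(a) == len(b) == len(bound)):
        raise ValueError("signal vectors and partition must cover all sites")
    delta = b - a
    d_bound = delta[bound]
    d_unbound = delta[~bound]
    if len(d_bound) == 0 or len(d_unbound) == 0:
        raise ValueError("partition must contain both bound and unbound sites")
    if np.all(delta == 0):
        p = 1.0
    else:
        p = wilcoxon_rank_sum(d_bound, d_unbound, two_sided=True)
    return {
        "delta_bound": d_bound,
        "delta_unbound": d_unbound,
        "p_value": p,
    }


def pairwise_set_counts(
    universe: Iterable[str],
    set_a: Iterable[str],
    set_b: Iterable[str],
    set_c: Optional[Iterable[str]] = None,
) -> Dict[str, int]:
    """Venn region counts of two or three subsets of a region universe.

    Counts sum to the size of the union of the subsets.
    """
    uni = set(universe)
    A, B = set(set_a) & uni, set(set_b) & uni
    if set_c is None:
        return {
            "A_only": len(A - B),
            "B_only": len(B - A),
            "AB": len(A & B),
        }
    C = set(set_c) & uni
    return {
        "A_only": len(A - B - C),
        "B_only": len(B - A - C),
        "C_only": len(C - A - B),
        "AB_only": len((A & B) - C),
        "AC_only": len((A & C) - B),
        "BC_only": len((B & C) - A),
        "ABC": len(A & B & C),
    }
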