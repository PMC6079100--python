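"""Enrichment normalization, RSA gene statistics and hit filters.

The per-guide pipeline is: pseudocounted normalization
``n_gs = (c_gs + 1) / T_s`` (``T_s`` = sum of raw counts in sample *s*),
then per-guide enrichment ``e_g = n_g,sorted / n_g,unsorted`` for each
sorted tail population against the unsorted reference.

Gene-level significance uses the redundant sgRNA activity (RSA)
statistic: rank all N guides by enrichment (most enriched first, ties
assigned the worst rank); for a gene whose n guides sit at ranks
r_1 < … < r_n, compute for each prefix i the hypergeometric tail
probability p_i = P(X >= i) with X ~ Hypergeom(N, n, r_i) — the chance
that at least i of the gene's guides land in the top r_i by luck — and
report p_min = min_i p_i.  The minimum over prefixes is not corrected for
multiplicity (the classical RSA definition), so p_min is a ranking score
that is anti-conservative as a p-value; hit calling uses the fixed
alpha = 0.01 convention.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import ScreenCounts

__all__ = [
    "normalize_counts",
    "guide_enrichment",
    "rsa_scores",
    "call_hits",
    "expression_filter",
    "signature_from_de",
]

logger = logging.getLogger(__name__)


def normalize_counts(counts: ScreenCounts) -> pd.DataFrame:
    """Pseudocounted per-sample normalization (c + 1) / T.

    T is the per-sample sum of *raw* counts; every normalized value is
    strictly positive.  Raises on an all-zero sample.
    """
    totals = counts.totals
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"sample(s) with zero total counts: {empty}")
    return (counts.counts + 1).div(totals, axis=1)


def guide_enrichment(
    normalized: pd.DataFrame,
    sorted_sample: str,
    reference_sample: str = "unsorted",
) -> pd.Series:
    """Per-guide enrichment: normalized(sorted) / normalized(unsorted)."""
    for name in (sorted_sample, reference_sample):
        if name not in normalized.columns:
            raise KeyError(f"unknown sample {name!r}")
    e = normalized[sorted_sample] / normalized[reference_sample]
    e.name = f"enrichment_{sorted_sample}"
    return e


def _rank_worst_ties(values: np.ndarray, ascending: bool) -> np.ndarray:
    """Ranks 1..N, best value first; tied values all get the worst
    (largest) rank of their block."""
    v = values if ascending else -values
    return stats.rankdata(v, method="max")


def rsa_scores(
    enrichment: pd.Series,
    guide_to_gene: Mapping[str, str],
    direction: str = "high",
    ascending: bool = False,
    lower_bound: Optional[float] = None,
    upper_bound: Optional[float] = None,
) -> pd.DataFrame:
    """RSA gene statistic over ranked guide enrichments.

    Parameters
    ----------
    enrichment
        Per-guide enrichment of one sorted population versus unsorted.
    guide_to_gene
        Mapping guide_id -> gene_id covering every guide in ``enrichment``.
    direction
        Label recorded in the output ('high' or 'low'); names the sorted
        population whose enrichment vector is being scored.  Ranking is
        by decreasing enrichment in both directions — a guide enriched in
        its tail population gets a good (small) rank.
    ascending
        Rank increasing enrichment first instead (scores depletion).
    lower_bound, upper_bound
        Optional activity bounds of the original RSA script; guides with
        enrichment outside the bounds still participate in N but cannot
        contribute a prefix.  Disabled (None) by default.

    Returns
    -------
    DataFrame indexed by gene with columns n_guides, best_rank, p_min,
    log_p and direction.
    """
    if len(enrichment) == 0:
        raise ValueError("empty enrichment input")
    guides = enrichment.index
    genes = pd.Series(
        [guide_to_gene[g] for g in guides], index=guides, name="gene_id"
    )
    N = len(enrichment)
    ranks = _rank_worst_ties(enrichment.to_numpy(float), ascending)

    eligible = np.ones(N, dtype=bool)
    if lower_bound is not None:
        eligible &= enrichment.to_numpy(float) >= lower_bound
    if upper_bound is not None:
        eligible &= enrichment.to_numpy(float) <= upper_bound

    records = []
    rank_series = pd.Series(ranks, index=guides)
    for gene, idx in genes.groupby(genes).groups.items():
        r_all = np.sort(rank_series.loc[idx].to_numpy())
        n = len(r_all)
        ok = np.sort(rank_series.loc[idx][eligible[guides.get_indexer(idx)]].to_numpy())
        if len(ok) == 0:
            p_min = 1.0
            best_rank = int(r_all[0])
        else:
            i = np.arange(1, len(ok) + 1)
            # P(X >= i) with X ~ Hypergeom(N, n marked, r_i drawn)
            p = stats.hypergeom.sf(i - 1, N, n, ok)
            p_min = float(np.clip(p.min(), np.finfo(float).tiny, 1.0))
            best_rank = int(ok[int(np.argmin(p))])
        records.append(
            {
                "gene_id": gene,
                "direction": direction,
                "n_guides": n,
                "best_rank": best_rank,
                "p_min": p_min,
                "log_p": float(np.log10(p_min)),
            }
        )
    result = pd.DataFrame.from_records(records).set_index("gene_id")
    return result.sort_values("p_min")


def call_hits(rsa: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Genes with p_min strictly below alpha, ascending by p_min."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    hits = rsa[rsa["p_min"] < alpha].sort_values("p_min")
    return hits


def expression_filter(
    hits: Sequence[str],
    expression: Mapping[str, float],
    threshold: float = 1.0,
) -> list:
    """Drop hit genes that are not expressed (RPKM below threshold).

    Genes absent from the expression map are treated as unexpressed,
    removed and logged.
    """
    kept = []
    for gene in hits:
        value = expression.get(gene)
        if value is None:
            logger.info("expression_filter: %s absent from expression map, "
                        "removed", gene)
            continue
        if value < threshold:
            continue
        kept.append(gene)
    return kept


def signature_from_de(
    stats_table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> set:
    """Upregulated signature: log2fc strictly above and fdr strictly below
    their thresholds.

    Expects columns ``gene``, ``log2fc`` and ``fdr`` (or a gene index).
    """
    cols = {"log2fc", "fdr"}
    if not cols <= set(stats_table.columns):
        raise ValueError(f"missing columns: {sorted(cols - set(stats_table.columns))}")
    table = stats_table
    if "gene" in table.columns:
        table = table.set_index("gene")
    mask = (table["log2fc"] > lfc_threshold) & (table["fdr"] < fdr_threshold)
    return set(table.index[mask])
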