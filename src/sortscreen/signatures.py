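"""Per-sample gene-signature activity scores and survival comparison.

The activity of a signature in one sample is summarised by a signed,
unweighted Kolmogorov–Smirnov statistic on the sample's gene ranking:
genes are z-scored across the cohort, ranked within the sample from
highest to lowest z, and the signature's running enrichment toward the
top (D+) and bottom (D-) of the list is compared; the score is D+ when
the set leans toward highly expressed genes and -D- otherwise.  Being
rank-based, the score is invariant under any strictly monotone transform
of a single sample's expression values.

Activity conventions follow the repressor/effector logic: a repressed
set scores activity as the *negated* enrichment of its genes (the
regulator is active when its targets are down), an induced set as the
plain enrichment.  Cohorts are stratified at the third quartile of a
score and compared with Kaplan–Meier curves and the log-rank test (a
1-df chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "sample_signature_score",
    "score_all_samples",
    "activity_scores",
    "spearman_rho",
    "quartile_stratify",
    "km_logrank",
    "wilcoxon_rank_sum",
    "SurvivalComparison",
]


def _zscore_rows(expression: pd.DataFrame) -> pd.DataFrame:
    mu = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=1)
    if (sd == 0).any():
        sd = sd.replace(0, np.nan)
    return expression.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def _ks_from_ranks(ranks: np.ndarray, n_genes: int) -> float:
    """Signed KS statistic for a set whose members sit at the given
    1-based ranks among n_genes."""
    r = np.sort(np.asarray(ranks, dtype=float))
    m = len(r)
    i = np.arange(1, m + 1)
    d_pos = np.max(i / m - (r - 1) / n_genes)
    d_neg = np.max(r / n_genes - (i - 1) / m)
    return float(d_pos if d_pos >= d_neg else -d_neg)


def sample_signature_score(
    expression: pd.DataFrame,
    gene_set: Iterable[str],
    sample: str,
    zscored: pd.DataFrame | None = None,
) -> float:
    """Signed KS enrichment of ``gene_set`` in one sample's ranking.

    Positive: the set is enriched among the sample's most highly
    expressed genes (cohort-z-scored).  Ties in z are broken by gene
    order.  ``zscored`` can pass a precomputed z-matrix to avoid
    recomputation when scoring many samples.
    """
    members = [g for g in gene_set if g in expression.index]
    if not members:
        raise ValueError("gene set has empty intersection with the matrix")
    z = _zscore_rows(expression) if zscored is None else zscored
    col = z[sample].to_numpy()
    order = np.argsort(-col, kind="stable")
    rank = np.empty(len(col), dtype=np.int64)
    rank[order] = np.arange(1, len(col) + 1)
    pos = expression.index.get_indexer(members)
    return _ks_from_ranks(rank[pos], len(col))


def score_all_samples(
    expression: pd.DataFrame, gene_set: Iterable[str]
) -> pd.Series:
    """Vector of signature scores, one per sample."""
    z = _zscore_rows(expression)
    return pd.Series(
        {
            s: sample_signature_score(expression, gene_set, s, zscored=z)
            for s in expression.columns
        },
        name="score",
    )


def activity_scores(
    expression: pd.DataFrame,
    trps1_repressed_set: Iterable[str],
    yap_induced_set: Iterable[str],
) -> pd.DataFrame:
    """Per-sample (trps1_activity, yap_activity).

    TRPS1 activity is the negated enrichment of its repressed targets
    (active repressor keeps them low); YAP activity is the plain
    enrichment of the genes induced on YAP hyperactivation.
    """
    repressed = score_all_samples(expression, trps1_repressed_set)
    induced = score_all_samples(expression, yap_induced_set)
    return pd.DataFrame(
        {"trps1_activity": -repressed, "yap_activity": induced}
    )


def spearman_rho(x, y) -> Tuple[float, float]:
    """Spearman rank correlation with average ties and t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def quartile_stratify(values) -> pd.Series:
    """'high' for values strictly above the third quartile
    (linear-interpolation quantile), 'low' for the remainder."""
    v = pd.Series(values)
    if len(v) < 4:
        raise ValueError("need at least four values to stratify by quartile")
    q3 = float(np.quantile(v.to_numpy(float), 0.75))
    labels = pd.Series(
        np.where(v.to_numpy(float) > q3, "high", "low"), index=v.index
    )
    return labels


@dataclass(frozen=True)
class SurvivalComparison:
    """Kaplan–Meier curves per group plus the log-rank chi-square test."""

    curves: dict            # group -> DataFrame (time, survival)
    chi_square: float       # log-rank statistic, 1 df
    p_value: float
    group_sizes: dict


def km_logrank(time, event, group) -> SurvivalComparison:
    """Product-limit survival curves per group and the log-rank test."""
    df = pd.DataFrame(
        {"time": np.asarray(time, float),
         "event": np.asarray(event, int),
         "group": np.asarray(group)}
    )
    if (df["time"] < 0).any():
        raise ValueError("times must be >= 0")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError("event must be 0/1")
    labels = df["group"].unique()
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    sizes = df["group"].value_counts().to_dict()
    if min(sizes.values()) == 0:
        raise ValueError("empty group")
    curves = {}
    for label in labels:
        sub = df[df["group"] == label]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    a = df[df["group"] == labels[0]]
    b = df[df["group"] == labels[1]]
    res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return SurvivalComparison(
        curves=curves,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=sizes,
    )


def wilcoxon_rank_sum(a, b, two_sided: bool = True) -> float:
    """Rank-sum (Mann–Whitney) p-value.

    Exact enumeration when the smaller sample has <= 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(a), len(b)) <= 8 and not has_ties
    alternative = "two-sided" if two_sided else "greater"
    res = stats.mannwhitneyu(
        a,
        b,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))
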