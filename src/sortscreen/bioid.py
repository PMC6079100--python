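"""Label-free differential abundance for proximity-biotinylation data.

The chain mirrors standard LFQ practice for two groups of three
replicates: proteins with fewer than two observed values in *both* groups
are dropped; the remaining missing cells are classified as MNAR
(intensity-dependent: one group has >= 2 missing while the other is fully
observed) or MAR (everything else); MNAR cells are imputed with the
minimum observed value of their sample column (MinDet), MAR cells with a
k-nearest-neighbour average; columns are quantile normalized; and
group differences are tested with a two-sample t whose variances are
shrunk by an empirical-Bayes scaled-F prior (hyperparameters d0, s0^2
estimated by the method of moments on log sample variances).  P-values
are adjusted with Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .simulate import LfqExperiment

__all__ = [
    "filter_protein_groups",
    "classify_missingness",
    "impute",
    "quantile_normalize",
    "moderated_t_test",
    "adjust_fdr",
    "differential_abundance",
    "ModeratedTResult",
]


def _group_columns(groups: pd.Series) -> Tuple[list, list]:
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    g1 = list(groups.index[groups == labels[0]])
    g2 = list(groups.index[groups == labels[1]])
    return g1, g2


def filter_protein_groups(
    intensities: pd.DataFrame, groups: pd.Series
) -> pd.Series:
    """Keep a protein unless it has < 2 observed values in both groups."""
    g1, g2 = _group_columns(groups)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two samples")
    obs1 = intensities[g1].notna().sum(axis=1)
    obs2 = intensities[g2].notna().sum(axis=1)
    kept = ~((obs1 < 2) & (obs2 < 2))
    kept.name = "kept"
    return kept


def classify_missingness(
    intensities: pd.DataFrame,
    groups: pd.Series,
    kept: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Label each missing cell of a kept protein as MNAR or MAR.

    MNAR: the cell's group has 2 or 3 missing values while the other
    group is fully observed — the asymmetry is taken as evidence of
    intensity-dependent dropout.  All other missing cells (including
    ambiguous mixed patterns) fall back to MAR, the conservative choice
    since MinDet injects extreme values.

    ``kept`` is the filter mask from :func:`filter_protein_groups`; it is
    required so classification can't silently run on unfiltered data.
    """
    if kept is None:
        raise ValueError(
            "run filter_protein_groups first and pass its mask as 'kept'"
        )
    g1, g2 = _group_columns(groups)
    data = intensities.loc[kept.reindex(intensities.index, fill_value=False)]
    labels = pd.DataFrame(
        "", index=data.index, columns=data.columns, dtype=object
    )
    for cols, other in ((g1, g2), (g2, g1)):
        miss = data[cols].isna()
        n_miss = miss.sum(axis=1)
        other_full = data[other].notna().all(axis=1)
        mnar_rows = (n_miss >= 2) & other_full
        for c in cols:
            labels.loc[mnar_rows & data[c].isna(), c] = "MNAR"
    remaining = data.isna() & (labels == "")
    labels = labels.mask(remaining, "MAR")
    return labels


def _masked_distances(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances over mutually observed entries.

    Entries with no mutual observation get +inf.
    """
    Z = np.where(mask, X, 0.0)
    M = mask.astype(float)
    sq = Z ** 2
    # sum over mutual entries of (xi - xj)^2
    d2 = sq @ M.T + M @ sq.T - 2.0 * (Z @ Z.T)
    shared = M @ M.T
    d2 = np.where(shared > 0, np.maximum(d2, 0.0), np.inf)
    return np.sqrt(d2)


def impute(
    intensities: pd.DataFrame,
    labels: pd.DataFrame,
    k: int = 10,
) -> pd.DataFrame:
    """Impute MNAR cells by MinDet and MAR cells by kNN.

    MinDet replaces a cell with the minimum observed value of its sample
    column.  kNN replaces a cell with the mean over the k nearest
    proteins (Euclidean distance on mutually observed entries, ties
    broken by protein order) that have an observed value in that column.
    """
    data = intensities.copy()
    if data.notna().all().all():
        return data
    observed = data.notna()
    no_obs = ~observed.any(axis=0)
    if no_obs.any():
        raise ValueError(
            f"sample column(s) with no observed values: "
            f"{list(data.columns[no_obs])}"
        )
    col_min = data.min(axis=0, skipna=True)

    # MinDet first
    for c in data.columns:
        rows = labels.index[(labels[c] == "MNAR")]
        data.loc[rows, c] = col_min[c]

    mar_cells = [
        (r, c)
        for c in data.columns
        for r in labels.index[labels[c] == "MAR"]
    ]
    if not mar_cells:
        return data

    X = intensities.to_numpy(float)
    mask = ~np.isnan(X)
    D = _masked_distances(X, mask)
    np.fill_diagonal(D, np.inf)
    row_pos = {r: i for i, r in enumerate(intensities.index)}
    col_pos = {c: j for j, c in enumerate(intensities.columns)}
    order = np.argsort(D, axis=1, kind="stable")  # ties: protein order
    for r, c in mar_cells:
        i, j = row_pos[r], col_pos[c]
        donors = []
        for cand in order[i]:
            if not np.isfinite(D[i, cand]):
                break
            if mask[cand, j]:
                donors.append(X[cand, j])
                if len(donors) == k:
                    break
        if not donors:
            # no neighbour observed at this column: fall back to column min
            donors = [col_min.iloc[j]]
        data.iloc[row_pos[r], col_pos[c]] = float(np.mean(donors))
    return data


def quantile_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of rank means.

    After normalization each column's sorted value vector equals the
    vector of row-wise means of the sorted input columns exactly; ties
    within a column keep their (stable) original order, which preserves
    the defining identical-sorted-columns property.
    """
    if intensities.isna().any().any():
        raise ValueError("quantile_normalize requires a complete matrix")
    X = intensities.to_numpy(float)
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[order[:, j], j] = reference
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeratedTResult:
    """Per-protein moderated-t table plus the fitted variance prior."""

    table: pd.DataFrame  # log_fc, t, p_value, fdr(optional), s2, s2_post, df_total
    d0: float            # prior degrees of freedom (may be inf)
    s0_sq: float         # prior variance


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df1: float) -> Tuple[float, float]:
    """Moment estimator of the scaled-F prior (s0_sq, d0) from sample
    variances with df1 residual degrees of freedom each."""
    s2 = np.asarray(s2, float)
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df1 / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(s0_sq), float(d0)


def moderated_t_test(
    intensities: pd.DataFrame,
    groups: pd.Series,
    d0_override: Optional[float] = None,
) -> ModeratedTResult:
    """Two-sample t-test with empirical-Bayes variance moderation.

    The pooled within-group variance s_g^2 (d_g degrees of freedom) is
    shrunk toward the prior s0^2 with weight d0:
    s~^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g), and
    t = (mean2 - mean1) / (s~ sqrt(1/n1 + 1/n2)) with d0 + d_g df.

    ``d0_override`` forces the prior weight (0 recovers the ordinary
    pooled t; inf forces s~^2 = s0^2 everywhere).
    """
    if intensities.isna().any().any():
        raise ValueError("moderated_t_test requires a complete matrix")
    g1, g2 = _group_columns(groups)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    X1 = intensities[g1].to_numpy(float)
    X2 = intensities[g2].to_numpy(float)
    delta = X2.mean(axis=1) - X1.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = X1.var(axis=1, ddof=1) * (n1 - 1) + X2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    if np.all(s2 <= 0):
        import warnings

        warnings.warn(
            "all within-group variances are zero; falling back to the "
            "ordinary t-test without moderation"
        )
        d0, s0_sq = 0.0, float("nan")
    elif d0_override is not None:
        d0 = float(d0_override)
        s0_sq, _ = _fit_f_dist(s2[s2 > 0], df_resid)
    else:
        s0_sq, d0 = _fit_f_dist(s2[s2 > 0], df_resid)

    if d0 == 0.0:
        s2_post = s2
        df_total = np.full_like(s2, df_resid)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = np.full_like(s2, d0 + df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    finite_df = np.isfinite(df_total)
    p = np.where(
        finite_df,
        2.0 * stats.t.sf(np.abs(t), np.where(finite_df, df_total, 1.0)),
        2.0 * stats.norm.sf(np.abs(t)),
    )
    table = pd.DataFrame(
        {
            "log_fc": delta,
            "t": t,
            "p_value": p,
            "s2": s2,
            "s2_post": s2_post,
            "df_total": df_total,
            "n_obs_g1": n1,
            "n_obs_g2": n2,
        },
        index=intensities.index,
    )
    return ModeratedTResult(table=table, d0=d0, s0_sq=s0_sq)


def adjust_fdr(pvalues, method: str = "BH") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone in p)."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    lookup = {"BH": "fdr_bh", "fdr_bh": "fdr_bh", "BY": "fdr_by",
              "bonferroni": "bonferroni"}
    if method not in lookup:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, alpha=0.05, method=lookup[method])[1]


def differential_abundance(
    experiment: LfqExperiment,
    k: int = 10,
    fdr_method: str = "BH",
) -> Tuple[pd.DataFrame, ModeratedTResult]:
    """Run the full chain: filter, classify, impute, quantile-normalize,
    moderated t, BH adjustment.

    Returns the per-protein result table (kept proteins only) and the
    underlying :class:`ModeratedTResult`.
    """
    data, groups = experiment.intensities, experiment.groups
    kept = filter_protein_groups(data, groups)
    labels = classify_missingness(data, groups, kept)
    completed = impute(data.loc[kept], labels, k=k)
    normalized = quantile_normalize(completed)
    result = moderated_t_test(normalized, groups)
    table = result.table.copy()
    table["fdr"] = adjust_fdr(table["p_value"].to_numpy(), method=fdr_method)
    table["n_mnar"] = (labels == "MNAR").sum(axis=1)
    table["n_mar"] = (labels == "MAR").sum(axis=1)
    return table, result
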