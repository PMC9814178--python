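"""Rank-based contrasts, effect sizes, FDR control and covariate-adjusted
richness.

Group contrasts use the Mann-Whitney test (two groups; exact enumeration
for small tie-free samples, tie-corrected normal approximation otherwise)
or Kruskal-Wallis (more than two groups). Effect sizes are Cliff's Delta.
Multiple testing is controlled with Benjamini-Hochberg; correlation panels
use Spearman's rho with two display tiers (q <= 0.1 strong, p <= 0.05
weak). Contingency tables get a Pearson chi-squared with Yates continuity
correction applied, by default, only to 2x2 tables. Richness adjustment is
ordinary-least-squares residualization on the covariates plus the grand
mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "ContrastResult",
    "rank_contrast",
    "contrast_table",
    "cliffs_delta",
    "bh_adjust",
    "spearman_panel",
    "chi_squared_table",
    "adjust_richness",
]

logger = logging.getLogger(__name__)

#: Largest per-group size for which the exact Mann-Whitney null is used.
EXACT_MW_MAX_N = 25


@dataclass
class ContrastResult:
    """Result of a single-feature group contrast."""

    feature_id: str
    group_labels: tuple[str, ...]
    p: float
    n_per_group: tuple[int, ...]
    statistic: float
    test: str
    cliffs_delta: float | None = None
    q: float | None = None

    @property
    def direction(self) -> int:
        """Sign of the effect (first group vs second); 0 for >2 groups."""
        if self.cliffs_delta is None:
            return 0
        return int(np.sign(self.cliffs_delta))


def cliffs_delta(x, y) -> float:
    """Cliff's Delta: (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y).

    Ties contribute zero. Antisymmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("cliffs_delta requires non-empty inputs")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()
    not_less = np.searchsorted(ys, x, side="right").sum()
    less = x.size * y.size - not_less
    return float(greater - less) / (x.size * y.size)


def rank_contrast(values, groups, feature_id: str = "feature") -> ContrastResult:
    """Two-group Mann-Whitney or k-group Kruskal-Wallis on one feature.

    Group labels are ordered by first appearance; Cliff's Delta (first vs
    second group) is reported for the two-group case only.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise DataError("values and groups must align")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise DataError("need at least two groups")
    parts = [values[groups == g] for g in labels]
    for g, part in zip(labels, parts):
        if part.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")

    if len(labels) == 2:
        x, y = parts
        pooled = np.concatenate([x, y])
        tie_free = np.unique(pooled).size == pooled.size
        small = x.size <= EXACT_MW_MAX_N and y.size <= EXACT_MW_MAX_N
        method = "exact" if (tie_free and small) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        delta = cliffs_delta(x, y)
        return ContrastResult(
            feature_id=feature_id,
            group_labels=tuple(str(g) for g in labels),
            p=float(res.pvalue),
            n_per_group=(x.size, y.size),
            statistic=float(res.statistic),
            test=f"mann-whitney-{method}",
            cliffs_delta=delta,
        )
    res = sps.kruskal(*parts)
    return ContrastResult(
        feature_id=feature_id,
        group_labels=tuple(str(g) for g in labels),
        p=float(res.pvalue),
        n_per_group=tuple(p.size for p in parts),
        statistic=float(res.statistic),
        test="kruskal-wallis",
    )


def contrast_table(features: pd.DataFrame, groups, q_threshold: float = 0.1) -> pd.DataFrame:
    """Per-feature contrasts over a feature x sample matrix, BH within the
    whole feature family. Returns a tidy frame sorted by q."""
    groups = pd.Series(np.asarray(groups), index=features.columns)
    rows = []
    for fid in features.index:
        r = rank_contrast(features.loc[fid].to_numpy(), groups.to_numpy(), feature_id=str(fid))
        rows.append(
            dict(feature=r.feature_id, p=r.p, cliffs_delta=r.cliffs_delta,
                 direction=r.direction, test=r.test,
                 n1=r.n_per_group[0], n2=r.n_per_group[1] if len(r.n_per_group) > 1 else None)
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] <= q_threshold
    return out.sort_values("q")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{k >= i} m * p_(k) / k, clipped at 1; monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman_panel(
    features: pd.DataFrame,
    variables: pd.DataFrame,
    q_threshold: float = 0.1,
    p_threshold: float = 0.05,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Spearman correlations of every feature against every variable.

    ``features`` is feature x sample; ``variables`` is sample x variable.
    Incomplete pairs are dropped cell-wise; cells with a constant vector or
    fewer than ``min_pairs`` complete pairs are recorded as missing. BH is
    applied across the whole panel (one family). Output columns: rho, p, q,
    n, strong (q tier), weak (p tier).
    """
    common = features.columns.intersection(variables.index)
    if len(common) < min_pairs:
        raise DataError("fewer shared samples than min_pairs")
    feats = features[common]
    vars_ = variables.loc[common]
    rows = []
    for fid in feats.index:
        fvals = feats.loc[fid]
        for var in vars_.columns:
            vvals = pd.to_numeric(vars_[var], errors="coerce")
            mask = fvals.notna() & vvals.notna()
            n = int(mask.sum())
            if n < min_pairs:
                rows.append((fid, var, np.nan, np.nan, n))
                continue
            xv = fvals[mask].to_numpy(dtype=float)
            yv = vvals[mask].to_numpy(dtype=float)
            if np.all(xv == xv[0]) or np.all(yv == yv[0]):
                logger.warning("spearman_panel: constant vector for (%s, %s)", fid, var)
                rows.append((fid, var, np.nan, np.nan, n))
                continue
            rho, p = sps.spearmanr(xv, yv)
            rows.append((fid, var, float(rho), float(p), n))
    out = pd.DataFrame(rows, columns=["feature", "variable", "rho", "p", "n"])
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    out["strong"] = out["q"] <= q_threshold
    out["weak"] = out["p"] <= p_threshold
    return out


def chi_squared_table(table, continuity: bool | None = None) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c table.

    ``continuity=None`` applies the Yates correction exactly when the table
    is 2x2; the correction is never applied to larger tables. Returns
    (statistic, df, p).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise DataError("need an r x c table with r, c >= 2")
    if (table < 0).any():
        raise DataError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("table has a zero margin")
    is_2x2 = table.shape == (2, 2)
    correct = is_2x2 if continuity is None else (continuity and is_2x2)
    res = sps.chi2_contingency(table, correction=correct)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            parts.append(series.astype(float))
        else:
            dummies = pd.get_dummies(series.astype("category"), prefix=col, drop_first=True)
            parts.extend(dummies[c].astype(float) for c in dummies.columns)
    return pd.concat(parts, axis=1)


def adjust_richness(richness: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS-residualize richness on the covariates, re-centred at the mean.

    Categorical covariates are one-hot encoded with the reference level
    dropped. Samples with any missing covariate are dropped (and logged). A
    rank-deficient design is an error naming the degenerate columns.
    """
    covariates = covariates.reindex(richness.index)
    complete = covariates.notna().all(axis=1) & richness.notna()
    if not complete.all():
        logger.warning("adjust_richness: dropping %d sample(s) with missing data",
                       int((~complete).sum()))
    y = richness[complete].astype(float)
    X = _design_matrix(covariates[complete])
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        bad = [X.columns[i] for i in range(mat.shape[1]) if abs(r[i, i]) < 1e-8]
        raise DataError(f"collinear design columns: {bad}")
    beta, *_ = np.linalg.lstsq(mat, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - mat @ beta
    return pd.Series(resid + y.mean(), index=y.index, name="adjusted_richness")
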