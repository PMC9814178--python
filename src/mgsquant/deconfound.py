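"""Covariate deconfounding of feature-status associations.

Each feature is first screened against status and every covariate with the
matching nonparametric test (Mann-Whitney for binary, Kruskal-Wallis for
categorical, Spearman for continuous), BH-corrected within each covariate's
family. Features whose status association survives are then classified by
nested rank-model likelihood-ratio tests against every other flagged
covariate: the status term must improve on a covariate-only model (status
retained) and vice versa. A feature is strictly deconfounded when status is
retained against every flagged covariate, confounded when some covariate
explains the status signal away while remaining informative itself, and
ambiguously deconfounded when neither model separates the two.

This is a re-derivation of the published three-label contract, not a
re-implementation of any particular package; both thresholds are
configurable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .stats import bh_adjust, rank_contrast

__all__ = [
    "LABELS",
    "naive_associations",
    "classify_confounding",
    "deconfound_features",
]

logger = logging.getLogger(__name__)

LABELS = ("not significant", "strictly deconfounded", "ambiguously deconfounded", "confounded")


def _covariate_kind(series: pd.Series) -> str:
    values = series.dropna()
    n_levels = values.nunique()
    if n_levels < 2:
        return "degenerate"
    if pd.api.types.is_numeric_dtype(values) and n_levels > 2:
        return "continuous"
    return "binary" if n_levels == 2 else "categorical"


def _single_association(feature: pd.Series, covariate: pd.Series, kind: str) -> float:
    mask = feature.notna() & covariate.notna()
    f = feature[mask].to_numpy(dtype=float)
    c = covariate[mask]
    if f.size < 4 or np.all(f == f[0]):
        return np.nan
    if kind == "continuous":
        rho, p = sps.spearmanr(f, c.to_numpy(dtype=float))
        return float(p)
    # drop group levels with a single observation; they carry no rank signal
    counts = c.value_counts()
    keep = c.isin(counts.index[counts >= 2])
    if c[keep].nunique() < 2:
        return np.nan
    result = rank_contrast(f[keep.to_numpy()], c[keep].to_numpy())
    return result.p


def naive_associations(
    features: pd.DataFrame, metadata: pd.DataFrame, threshold: float = 0.1
) -> pd.DataFrame:
    """Screen every feature against every metadata column.

    Returns a long frame (feature, covariate, kind, p, q, flagged) with BH
    applied within each covariate's family of features. Single-level
    covariates are skipped with a warning; constant features yield missing
    p-values.
    """
    common = features.columns.intersection(metadata.index)
    if len(common) < 4:
        raise DataError("too few shared samples between features and metadata")
    feats = features[common]
    meta = metadata.loc[common]
    blocks = []
    for cov in meta.columns:
        kind = _covariate_kind(meta[cov])
        if kind == "degenerate":
            logger.warning("naive_associations: covariate %r has a single level; skipped", cov)
            continue
        pvals = np.array([
            _single_association(feats.loc[fid], meta[cov], kind) for fid in feats.index
        ])
        block = pd.DataFrame({
            "feature": feats.index, "covariate": cov, "kind": kind, "p": pvals,
        })
        valid = block["p"].notna()
        q = np.full(len(block), np.nan)
        if valid.any():
            q[valid.to_numpy()] = bh_adjust(block.loc[valid, "p"].to_numpy())
        block["q"] = q
        blocks.append(block)
    if not blocks:
        raise DataError("no usable covariates")
    out = pd.concat(blocks, ignore_index=True)
    out["flagged"] = out["q"] <= threshold
    return out


def _encode(series: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
        return series.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(series.astype("category"), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _lrt_p(y: np.ndarray, X0: np.ndarray, X1: np.ndarray) -> float:
    """Likelihood-ratio p for nested Gaussian linear models (X0 in X1)."""
    n = y.size
    rss0, rss1 = _rss(y, X0), _rss(y, X1)
    df = X1.shape[1] - X0.shape[1]
    if df <= 0:
        raise DataError("models are not strictly nested")
    if rss1 <= 0:
        return 0.0
    lr = n * np.log(rss0 / rss1)
    return float(sps.chi2.sf(lr, df))


def classify_confounding(
    feature: pd.Series,
    status: pd.Series,
    flagged_covariates: pd.DataFrame,
    threshold: float = 0.05,
) -> tuple[str, list[str]]:
    """Label one status-significant feature against its flagged covariates.

    For each covariate C, nested rank-linear models decide whether status
    improves on C (status retained) and whether C improves on status
    (covariate retained). Strictly deconfounded when status is retained
    everywhere (vacuously true with no flagged covariates); confounded when
    some C drops status while being retained itself; ambiguous otherwise.
    Returns (label, implicated covariates).
    """
    if flagged_covariates.empty or flagged_covariates.shape[1] == 0:
        return "strictly deconfounded", []
    mask = feature.notna() & status.notna() & flagged_covariates.notna().all(axis=1)
    y = sps.rankdata(feature[mask].to_numpy(dtype=float))
    s_enc = _encode(status[mask])
    ones = np.ones((y.size, 1))
    confounded_by: list[str] = []
    ambiguous_with: list[str] = []
    for cov in flagged_covariates.columns:
        c_enc = _encode(flagged_covariates.loc[mask, cov])
        X_c = np.hstack([ones, c_enc])
        X_s = np.hstack([ones, s_enc])
        X_sc = np.hstack([ones, c_enc, s_enc])
        if np.linalg.matrix_rank(X_c) < X_c.shape[1]:
            raise DataError(f"degenerate rank design for covariate {cov!r}")
        rank_c = np.linalg.matrix_rank(X_c)
        rank_sc = np.linalg.matrix_rank(X_sc)
        if rank_sc == rank_c:
            # covariate structurally aliases status (e.g. a treatment column
            # that identifies controls exactly): the two cannot be separated
            ambiguous_with.append(cov)
            continue
        status_retained = _lrt_p(y, X_c, X_sc) <= threshold
        cov_retained = _lrt_p(y, X_s, X_sc) <= threshold
        if status_retained:
            continue
        if cov_retained:
            confounded_by.append(cov)
        else:
            ambiguous_with.append(cov)
    if confounded_by:
        return "confounded", confounded_by
    if ambiguous_with:
        return "ambiguously deconfounded", ambiguous_with
    return "strictly deconfounded", []


def deconfound_features(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    status_col: str,
    covariates: list[str] | None = None,
    q_threshold: float = 0.1,
    lrt_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full labelling of every feature: screen, then classify.

    Returns a frame indexed by feature with naive_p, naive_q (status
    association), label and implicated_covariates (comma-joined).
    """
    if status_col not in metadata.columns:
        raise DataError(f"status column {status_col!r} not in metadata")
    covariates = [c for c in (covariates or list(metadata.columns)) if c != status_col]
    screen = naive_associations(
        features, metadata[[status_col] + covariates], threshold=q_threshold
    )
    status_block = screen[screen["covariate"] == status_col].set_index("feature")
    common = features.columns.intersection(metadata.index)
    rows = []
    for fid in features.index:
        naive_p = status_block.at[fid, "p"]
        naive_q = status_block.at[fid, "q"]
        if not status_block.at[fid, "flagged"]:
            rows.append((fid, naive_p, naive_q, "not significant", ""))
            continue
        flagged = screen[
            (screen["feature"] == fid) & screen["flagged"] & (screen["covariate"] != status_col)
        ]["covariate"].tolist()
        label, implicated = classify_confounding(
            features.loc[fid, common],
            metadata.loc[common, status_col],
            metadata.loc[common, flagged],
            threshold=lrt_threshold,
        )
        rows.append((fid, naive_p, naive_q, label, ",".join(implicated)))
    return pd.DataFrame(
        rows, columns=["feature", "naive_p", "naive_q", "label", "implicated_covariates"]
    ).set_index("feature")
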