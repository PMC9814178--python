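"""Beta diversity (Bray-Curtis on log10 abundances), PCoA, PERMANOVA and
alpha diversity.

Abundances are shifted-log transformed with a pseudocount (default half the
smallest positive value) so zeros map to zero, Bray-Curtis is computed on
the transformed profiles, ordination is classical metric scaling and group
separation is tested by a permutation pseudo-F on the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DataError
from .quantify import MgsAbundanceMatrix

__all__ = [
    "bray_curtis_log10",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "pairwise_permanova",
    "alpha_diversity",
]


def default_pseudocount(values: np.ndarray) -> float:
    positive = values[values > 0]
    if positive.size == 0:
        raise DataError("all abundances are zero; no pseudocount derivable")
    return float(positive.min() / 2.0)


def bray_curtis_log10(
    ab: MgsAbundanceMatrix | pd.DataFrame, pseudocount: float | None = None
) -> pd.DataFrame:
    """Bray-Curtis dissimilarity on log10-transformed abundances.

    y = log10(a + pc) - log10(pc), so zero abundances transform to exactly
    zero and all values are non-negative; BC(i, j) = sum|y_i - y_j| /
    sum(y_i + y_j). The pseudocount defaults to half the smallest positive
    abundance in the matrix.
    """
    values = ab.values if isinstance(ab, MgsAbundanceMatrix) else ab
    mat = values.to_numpy(dtype=float)
    if pseudocount is None:
        pseudocount = default_pseudocount(mat)
    if pseudocount <= 0:
        raise DataError("pseudocount must be > 0")
    empty = (mat > 0).sum(axis=0) == 0
    if empty.any():
        bad = values.columns[empty][0]
        raise DataError(f"sample {bad!r} has all-zero abundances; distance undefined")
    y = np.log10(mat + pseudocount) - np.log10(pseudocount)
    dist = squareform(pdist(y.T, metric="braycurtis"))
    return pd.DataFrame(dist, index=values.columns, columns=values.columns)


def pcoa(d: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and scales eigenvectors of
    positive eigenvalues by their square roots. Negative eigenvalues are
    returned but never used for coordinates. Returns (coordinates with
    columns PCo1..PCok, all eigenvalues in decreasing order).
    """
    mat = d.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10):
        raise DataError("distance matrix must be square and symmetric")
    n = mat.shape[0]
    if k > n - 1:
        raise DataError(f"k={k} exceeds n-1={n - 1}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (mat**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = np.abs(eigval).max() * 1e-12 if eigval.size else 0.0
    coords = np.zeros((n, k))
    for axis in range(k):
        if eigval[axis] > tol:
            coords[:, axis] = eigvec[:, axis] * np.sqrt(eigval[axis])
    frame = pd.DataFrame(coords, index=d.index,
                         columns=[f"PCo{i + 1}" for i in range(k)])
    return frame, eigval


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p: float
    n_permutations: int
    seed: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    d: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix with free label permutation.

    pseudo-F = ((SS_total - SS_within) / (k - 1)) / (SS_within / (n - k))
    with SS terms computed from squared distances; the p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    groups = pd.Series(np.asarray(groups), index=d.index)
    codes, labels = pd.factorize(groups)
    n_groups = len(labels)
    if n_groups < 2:
        raise DataError("need at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = labels[np.argmin(counts)]
        raise DataError(f"group {small!r} has fewer than 2 samples")
    d2 = d.to_numpy(dtype=float) ** 2
    f_obs, r2 = _pseudo_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, rng.permutation(codes), n_groups)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r_squared=float(r2), p=float(p),
                           n_permutations=n_perm, seed=seed)


def pairwise_permanova(
    d: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """PERMANOVA for every unordered group pair, BH-adjusted across pairs."""
    from .stats import bh_adjust

    groups = pd.Series(np.asarray(groups), index=d.index)
    sizes = groups.value_counts()
    labels = [g for g in pd.unique(groups) if sizes[g] >= 2]
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            mask = groups.isin([a, b])
            sub = d.loc[mask, mask]
            res = permanova(sub, groups[mask], n_perm=n_perm, seed=seed)
            rows.append(dict(group1=str(a), group2=str(b), pseudo_f=res.pseudo_f,
                             r_squared=res.r_squared, p=res.p,
                             n_permutations=n_perm))
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def alpha_diversity(matrix: pd.DataFrame, chao1: bool = False) -> pd.DataFrame:
    """Per-sample richness, Shannon entropy and (optionally) Chao1.

    Shannon H = -sum p ln p over positive proportions. Chao1 = S_obs +
    F1(F1 - 1) / (2 (F2 + 1)) and requires integer counts; passing
    non-count data is an error telling the caller to integerize first.
    """
    mat = matrix.to_numpy(dtype=float)
    if (mat < 0).any():
        raise DataError("abundances must be non-negative")
    richness = (mat > 0).sum(axis=0)
    shannon = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        col = mat[:, j]
        total = col.sum()
        if total > 0:
            p = col[col > 0] / total
            shannon[j] = float(-(p * np.log(p)).sum())
    out = pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon}, index=matrix.columns
    )
    if chao1:
        if not np.allclose(mat, np.rint(mat)):
            raise DataError(
                "Chao1 requires integer counts; integerize (e.g. round or rarefy) first"
            )
        ints = np.rint(mat).astype(int)
        f1 = (ints == 1).sum(axis=0)
        f2 = (ints == 2).sum(axis=0)
        out["chao1"] = richness + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return out
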