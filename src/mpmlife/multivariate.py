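"""Imputation, phylogenetically-corrected PCA and the inferential models.

Missing trait values are completed by multivariate imputation by chained
equations (MICE) with predictive mean matching: each incomplete column is
regressed on all others, and every missing entry receives the observed value
of a donor whose regression prediction is closest — imputed values are always
real observed values, preserving each trait's support and distribution.

Species trait values are not independent draws: close relatives resemble each
other.  The PCA therefore uses the Brownian-motion phylogenetic covariance
Cmat (shared root-to-MRCA branch length between each pair of species), GLS
ancestral means a = (1ᵀCmat⁻¹1)⁻¹ 1ᵀCmat⁻¹X, and the evolutionary covariance
R = (X−1a)ᵀ Cmat⁻¹ (X−1a)/(N−1), whose eigenvectors give the loadings.  On a
star phylogeny with equal branch lengths this reduces exactly to ordinary
PCA.  Axes are retained by the Kaiser criterion (eigenvalue > 1 on
standardized traits).

The inferential stage mirrors a comparative senescence analysis: ordinary
least squares of Keyfitz entropy H on the two retained axis scores (with
interaction), the same with a clonality covariate, one-sample t-tests of each
reproduction-mode group's mean H against the negligible-senescence threshold
H = 1, and Tukey HSD contrasts between modes with a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .mpm_core import ContractViolation
from .traits import TraitMatrix

__all__ = [
    "PCAResult",
    "RegressionResult",
    "impute_missing",
    "phylo_pca",
    "ordinary_pca",
    "retain_axes_kaiser",
    "regress_entropy_on_scores",
    "clonality_covariate_models",
    "group_entropy_tests",
    "tukey_by_mode",
    "phylo_covariance",
]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # traits × axes
    scores: pd.DataFrame  # species × axes
    eigenvalues: np.ndarray
    pct_var: np.ndarray
    retained: list[int] = field(default_factory=list)


@dataclass
class RegressionResult:
    model: str
    table: pd.DataFrame  # rows: term, estimate, SE, t, P
    n: int
    r_squared: float = float("nan")


# ---------------------------------------------------------------------------
# imputation: MICE with predictive mean matching
# ---------------------------------------------------------------------------

def impute_missing(
    tm: TraitMatrix,
    n_iter: int = 10,
    donors: int = 5,
    seed: int = 0,
) -> TraitMatrix:
    """Complete the trait matrix by chained equations with PMM.

    Missing entries start at their column means; then for ``n_iter`` sweeps
    each incomplete column is regressed (OLS) on all other columns over its
    observed rows, and every missing entry is replaced by the observed value
    of one of the ``donors`` rows whose predictions sit closest to the
    missing row's prediction (drawn uniformly, seeded).  A complete matrix is
    returned unchanged.
    """
    X = tm.values.to_numpy(dtype=float).copy()
    miss = ~np.isfinite(X)
    if not miss.any():
        return tm
    n, p = X.shape
    for j in range(p):
        obs = ~miss[:, j]
        if obs.sum() < p + 1:
            raise ContractViolation(
                f"column {tm.values.columns[j]!r} has only {int(obs.sum())} observed "
                f"values; too few to regress on {p - 1} predictors"
            )
        if obs.sum() < n:
            X[miss[:, j], j] = X[obs, j].mean()

    rng = np.random.default_rng(seed)
    incomplete = [j for j in range(p) if miss[:, j].any()]
    for _ in range(n_iter):
        for j in incomplete:
            obs = ~miss[:, j]
            others = [k for k in range(p) if k != j]
            design_obs = np.column_stack([np.ones(obs.sum()), X[np.ix_(obs, others)]])
            beta, *_ = np.linalg.lstsq(design_obs, X[obs, j], rcond=None)
            design_all = np.column_stack([np.ones(n), X[:, others]])
            pred = design_all @ beta
            obs_idx = np.flatnonzero(obs)
            for i in np.flatnonzero(miss[:, j]):
                d = np.abs(pred[obs_idx] - pred[i])
                k = min(donors, obs_idx.size)
                pool = obs_idx[np.argsort(d, kind="stable")[:k]]
                X[i, j] = X[rng.choice(pool), j]

    out = TraitMatrix(
        values=pd.DataFrame(X, index=tm.values.index, columns=tm.values.columns),
        mask=tm.mask.copy(),
        logged=tm.logged,
        standardized=tm.standardized,
        outliers_masked=tm.outliers_masked,
        log_eps=dict(tm.log_eps),
        outlier_bounds=dict(tm.outlier_bounds),
        col_means=tm.col_means,
        col_stds=tm.col_stds,
        H=tm.H,
        modes=tm.modes,
    )
    return out


# ---------------------------------------------------------------------------
# phylogenetically-corrected PCA
# ---------------------------------------------------------------------------

def phylo_covariance(tree, taxa: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance among tips: Cmat[i, j] = branch length
    shared from the root to the MRCA of tips i and j."""
    labels = {}
    for leaf in tree.leaf_node_iter():
        labels[leaf.taxon.label] = leaf
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise ContractViolation(f"tips missing from tree: {missing[:5]}")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    root_dist = {t: labels[t].root_distance for t in taxa}
    C = np.empty((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = root_dist[a]
        for j in range(i + 1, n):
            b = taxa[j]
            d = pdm.patristic_distance(labels[a].taxon, labels[b].taxon)
            C[i, j] = C[j, i] = 0.5 * (root_dist[a] + root_dist[b] - d)
    return C


def _pca_from_cov(R: np.ndarray, centered: np.ndarray, tm: TraitMatrix) -> PCAResult:
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for k in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, k]))
        if vecs[pivot, k] < 0:
            vecs[:, k] = -vecs[:, k]
    scores = centered @ vecs
    axes = [f"PC{i + 1}" for i in range(len(vals))]
    pct = 100.0 * vals / vals.sum()
    res = PCAResult(
        loadings=pd.DataFrame(vecs, index=tm.values.columns, columns=axes),
        scores=pd.DataFrame(scores, index=tm.values.index, columns=axes),
        eigenvalues=vals,
        pct_var=pct,
    )
    res.retained = retain_axes_kaiser(res)
    return res


def ordinary_pca(tm: TraitMatrix) -> PCAResult:
    """Plain covariance PCA on the (standardized) trait matrix."""
    X = tm.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ContractViolation("trait matrix must be complete; impute first")
    centered = X - X.mean(axis=0)
    R = centered.T @ centered / (X.shape[0] - 1)
    return _pca_from_cov(R, centered, tm)


def phylo_pca(tm: TraitMatrix, tree) -> PCAResult:
    """Phylogenetically-corrected PCA under a Brownian-motion tree covariance.

    Tip labels must match the trait-matrix index one-to-one (extra tree tips
    are ignored, missing ones are an error).  Non-positive-definite Cmat —
    e.g. duplicated zero-length tips — is an error.
    """
    X = tm.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ContractViolation("trait matrix must be complete; impute first")
    taxa = list(tm.values.index)
    C = phylo_covariance(tree, taxa)
    try:
        cho = scipy.linalg.cho_factor(C)
    except np.linalg.LinAlgError as e:
        raise ContractViolation(f"phylogenetic covariance not positive definite: {e}")
    one = np.ones((len(taxa), 1))
    Cinv_X = scipy.linalg.cho_solve(cho, X)
    Cinv_1 = scipy.linalg.cho_solve(cho, one)
    a = (one.T @ Cinv_X) / (one.T @ Cinv_1)
    centered = X - a
    R = centered.T @ scipy.linalg.cho_solve(cho, centered) / (X.shape[0] - 1)
    return _pca_from_cov(R, centered, tm)


def retain_axes_kaiser(p: PCAResult) -> list[int]:
    """Kaiser criterion: keep axes with eigenvalue strictly greater than 1,
    in decreasing eigenvalue order (0-based indices)."""
    return [int(i) for i in np.flatnonzero(p.eigenvalues > 1.0)]


# ---------------------------------------------------------------------------
# inferential models
# ---------------------------------------------------------------------------

def _ols_table(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "SE": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "P": fit.pvalues.to_numpy(),
        }
    ).reset_index(drop=True)


def regress_entropy_on_scores(
    H: pd.Series,
    scores: pd.DataFrame,
    subset: Optional[pd.Series] = None,
    min_n: int = 10,
) -> RegressionResult:
    """OLS of Keyfitz entropy on the first two axis scores with interaction:
    H ~ PC1 + PC2 + PC1×PC2.  ``subset`` is an optional boolean mask (e.g. one
    reproduction mode)."""
    df = pd.DataFrame({"H": H, "PC1": scores.iloc[:, 0], "PC2": scores.iloc[:, 1]})
    if subset is not None:
        df = df[subset.reindex(df.index).fillna(False).astype(bool)]
    df = df.dropna()
    if len(df) < min_n:
        raise ContractViolation(f"only {len(df)} species in subset; need >= {min_n}")
    fit = smf.ols("H ~ PC1 + PC2 + PC1:PC2", data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ContractViolation("design matrix is rank deficient")
    return RegressionResult(
        model="H ~ PC1 + PC2 + PC1:PC2",
        table=_ols_table(fit),
        n=len(df),
        r_squared=float(fit.rsquared),
    )


def clonality_covariate_models(
    H: pd.Series,
    scores: pd.DataFrame,
    clonal: pd.Series,
    min_n: int = 10,
) -> dict[str, RegressionResult]:
    """The three clonality-covariate models:

    A: H ~ PC1 + PC2 + clonal + PC1×clonal + PC2×clonal
    B: H ~ PC1 × clonal
    C: H ~ PC2 × clonal
    """
    df = pd.DataFrame(
        {
            "H": H,
            "PC1": scores.iloc[:, 0],
            "PC2": scores.iloc[:, 1],
            "clonal": clonal.reindex(H.index).astype(float),
        }
    ).dropna()
    if len(df) < min_n:
        raise ContractViolation(f"only {len(df)} species; need >= {min_n}")
    if df["clonal"].nunique() < 2:
        raise ContractViolation("clonality vector has a single class")
    formulas = {
        "A": "H ~ PC1 + PC2 + clonal + PC1:clonal + PC2:clonal",
        "B": "H ~ PC1 * clonal",
        "C": "H ~ PC2 * clonal",
    }
    out = {}
    for key, formula in formulas.items():
        fit = smf.ols(formula, data=df).fit()
        out[key] = RegressionResult(
            model=formula, table=_ols_table(fit), n=len(df), r_squared=float(fit.rsquared)
        )
    return out


def group_entropy_tests(H: pd.Series, modes: pd.Series, mu0: float = 1.0) -> pd.DataFrame:
    """Per reproduction-mode one-sample two-sided t-test of mean H against the
    negligible-senescence threshold H = ``mu0``.  Returns one row per group
    with (n, mean, SE, df, t, P)."""
    df = pd.DataFrame({"H": H, "mode": modes.reindex(H.index)}).dropna()
    rows = []
    for mode, grp in df.groupby("mode", sort=True):
        x = grp["H"].to_numpy(dtype=float)
        if x.size < 2:
            raise ContractViolation(f"group {mode!r} has fewer than 2 species")
        mean = float(x.mean())
        se = float(x.std(ddof=1) / np.sqrt(x.size))
        dfree = x.size - 1
        if se == 0.0:
            t = 0.0 if mean == mu0 else np.inf * np.sign(mean - mu0)
        else:
            t = (mean - mu0) / se
        p = 2.0 * scipy.stats.t.sf(abs(t), dfree)
        rows.append(
            {"mode": mode, "n": x.size, "mean": mean, "SE": se, "df": dfree, "t": t, "P": p}
        )
    return pd.DataFrame(rows)


def _compact_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff they belong to a
    common maximal clique of the not-significantly-different graph."""
    g = nx.Graph()
    g.add_nodes_from(groups)
    for pair in not_different:
        a, b = tuple(pair)
        g.add_edge(a, b)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(g)),
        key=lambda c: (groups.index(c[0]), c),
    )
    letters = {grp: "" for grp in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for grp in clique:
            letters[grp] += alphabet[i % len(alphabet)]
    return {g_: "".join(sorted(v)) for g_, v in letters.items()}


def tukey_by_mode(
    values: pd.Series, modes: pd.Series, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tukey HSD over a one-way reproduction-mode layout plus a compact
    letter display at the given α.  Returns (pairwise table, letters)."""
    df = pd.DataFrame({"y": values, "g": modes.reindex(values.index)}).dropna()
    counts = df["g"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ContractViolation("need >= 2 groups with >= 2 observations each")
    res = pairwise_tukeyhsd(df["y"].to_numpy(), df["g"].to_numpy(), alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    groups = sorted(counts.index)
    nd = set()
    for (a, b), reject in zip(
        [(r[0], r[1]) for r in res.summary().data[1:]], res.reject
    ):
        if not reject:
            nd.add(frozenset((str(a), str(b))))
    letters = _compact_letters(groups, nd)
    return table, letters
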