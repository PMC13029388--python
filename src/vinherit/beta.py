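"""Bray-Curtis dissimilarity, principal coordinates analysis and PERMANOVA.

PCoA is classical (Gower) scaling: double-centre ``-D^2/2``, keep the
eigenvectors with positive eigenvalues, report the negative-eigenvalue
mass without applying any correction.

PERMANOVA follows Anderson's pseudo-F on the squared-distance partition.
Two modes are offered: *marginal* fits each factor separately (the way
single-factor R^2 values are usually quoted) and *sequential* adds terms
in the user's order with Type-I sums of squares.  Permutations are free
(unrestricted) shuffles of sample labels by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from vinherit.core_io import CommunityTable, DistanceMatrix, ValidationError


@dataclass
class OrdinationResult:
    """PCoA embedding: samples x axes, eigenvalues sorted descending."""

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def bray_curtis(table: CommunityTable, normalize: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis D_jk = sum|x_ij - x_ik| / sum(x_ij + x_ik).

    By default abundances are column-normalized first (relative
    abundances); ``normalize=False`` works on the raw values.
    """
    if table.n_samples < 2:
        raise ValidationError("need at least two samples")
    X = table.relative_abundance() if normalize else table.counts.astype(float)
    totals = X.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValidationError(f"sample {table.sample_ids[zero[0]]!r} has zero total")
    D = squareform(pdist(X.T, metric="braycurtis"))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(table.sample_ids), np.clip(D, 0.0, 1.0), "braycurtis")


def pcoa(dm: DistanceMatrix, eig_rtol: float = 1e-8) -> OrdinationResult:
    """Classical scaling of a dissimilarity matrix.

    Axes with eigenvalue > ``eig_rtol * max_eigenvalue`` are retained.
    For a Euclidean-embeddable input the inter-point distances along the
    retained axes reproduce the input exactly.
    """
    n = len(dm.sample_ids)
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    A = -0.5 * dm.data**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eig_rtol * max(eigvals.max(), 0.0)
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    pos_sum = eigvals[eigvals > 0].sum()
    neg_mass = float(-eigvals[eigvals < 0].sum())
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=eigvals[keep] / pos_sum,
        negative_eigenvalue_mass=neg_mass,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _gower(dm: DistanceMatrix) -> np.ndarray:
    n = dm.data.shape[0]
    A = -0.5 * dm.data**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _design(meta: pd.DataFrame, factors: list[str]) -> np.ndarray:
    """Intercept + dummy columns for every factor (and nothing else)."""
    X = [np.ones((len(meta), 1))]
    for f in factors:
        X.append(pd.get_dummies(meta[f], drop_first=True).to_numpy(dtype=float))
    return np.hstack(X)


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factors: list[str] | str,
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "marginal",
    strata: str | None = None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Parameters
    ----------
    factors
        Metadata column(s).  ``mode="marginal"`` fits each factor alone
        (R^2 = SS_between / SS_total); ``mode="sequential"`` partitions
        with Type-I sums of squares in the given order.
    strata
        Optional metadata column restricting permutations to shuffle
        within its levels.

    Returns a table with one row per term: df, SS, pseudo-F, R2 and the
    permutation p-value ``(1 + #{F* >= F}) / (1 + n_perm)``.
    """
    if isinstance(factors, str):
        factors = [factors]
    meta = metadata.loc[dm.sample_ids]
    for f in factors:
        levels = meta[f].value_counts()
        if len(levels) < 2:
            raise ValidationError(f"factor {f!r} is constant")
        if (levels == 1).any():
            warnings.warn(f"factor {f!r} has a level with a single sample", stacklevel=2)

    G = _gower(dm)
    ss_total = float(np.trace(G))
    n = G.shape[0]
    rng = np.random.default_rng(seed)

    if strata is not None:
        groups = [np.flatnonzero(meta[strata].values == lev) for lev in pd.unique(meta[strata])]

        def permute() -> np.ndarray:
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(len(g))]
            return perm
    else:
        def permute() -> np.ndarray:
            return rng.permutation(n)

    def fit(hats: list[np.ndarray], dfs: list[int], Gm: np.ndarray) -> tuple[list[float], list[float]]:
        """Sequential SS per term and F statistics for a nested hat chain."""
        traces = [float((H * Gm).sum()) for H in hats]  # tr(H G), H symmetric
        ss_terms = [traces[0]] + [traces[i] - traces[i - 1] for i in range(1, len(traces))]
        total = float(np.trace(Gm))
        # cancellation can leave a tiny negative residual when the model
        # explains everything; clamp so F degenerates to +inf, not -huge
        ss_res = max(total - traces[-1], 0.0)
        df_res = n - 1 - sum(dfs)
        denom = ss_res / df_res
        tiny = 1e-12 * max(abs(total), 1.0)
        fs = [np.inf if denom <= tiny else (ss / df) / denom for ss, df in zip(ss_terms, dfs)]
        return ss_terms, fs

    rows = []
    if mode == "marginal":
        term_sets = [[f] for f in factors]
    elif mode == "sequential":
        term_sets = [factors]
    else:
        raise ValueError("mode must be 'marginal' or 'sequential'")

    for terms in term_sets:
        hats, dfs = [], []
        for k in range(1, len(terms) + 1):
            X = _design(meta, terms[:k])
            hats.append(_hat(X) - np.ones((n, n)) / n)  # centre out the intercept
            dfs.append(int(np.linalg.matrix_rank(X)) - 1 - sum(dfs))
        ss_terms, f_obs = fit(hats, dfs, G)
        exceed = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = permute()
            Gp = G[np.ix_(perm, perm)]
            _, f_perm = fit(hats, dfs, Gp)
            exceed += np.asarray(f_perm) >= np.asarray(f_obs)
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        df_res = n - 1 - sum(dfs)
        ss_res = ss_total - sum(ss_terms)
        for term, df, ss, F, p in zip(terms, dfs, ss_terms, f_obs, pvals):
            rows.append(dict(term=term, mode=mode, df=df, SS=ss, pseudo_F=F,
                             R2=ss / ss_total, p_value=p, n_perm=n_perm, seed=seed))
        rows.append(dict(term="Residual" if mode == "sequential" else f"Residual({terms[0]})",
                         mode=mode, df=df_res, SS=ss_res, pseudo_F=np.nan,
                         R2=ss_res / ss_total, p_value=np.nan, n_perm=n_perm, seed=seed))
    return pd.DataFrame(rows)
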