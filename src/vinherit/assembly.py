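"""Deterministic vs. stochastic assembly between mothers and daughters.

Three layers:

* **betaMNTD / betaNTI** — abundance-weighted mean nearest-taxon
  phylogenetic turnover between two samples, standardized against a
  taxa-shuffle null (tip labels permuted across the whole tree,
  abundances fixed).  |betaNTI| > 2 is the conventional signature of
  deterministic assembly; the value is reported, never enforced.

* **NST** — the normalized stochasticity ratio.  For a sample pair with
  observed similarity G = 1 - D and null expected similarity E, the
  selection strength is ``SS = (G - E)/(1 - E)`` when G >= E (selection
  homogenizes) and ``SS = (E - G)/E`` otherwise (variable selection
  diverges), and the stochasticity of the pair is ``ST = 1 - SS``.  A
  family's NST is the mean ST over its within-family pairs, clamped to
  [0, 1]; values above 50% read as predominantly stochastic assembly,
  below 50% as deterministic.  The null ("PF" model) fixes each sample's
  richness, draws taxa with probability proportional to their occupancy
  frequency, and reassigns abundances proportional to the regional mean
  relative abundance.  Null expectations are computed once per stratum
  and shared across families, which keeps the mother-daughter
  permutation test exact and affordable.

* **mother-daughter permutation test** — the stratum's daughters are
  repeatedly reassigned to mothers uniformly at random, preserving
  family sizes, giving a null distribution for any per-family statistic
  (mean betaNTI or NST); reported as Z-scores with two-sided permutation
  p-values and significance stars (* < 0.05, ** < 0.01, *** < 0.001).
  Reassignment never crosses strata: mixing chateaux would conflate the
  site effect with the inheritance null.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from vinherit.core_io import (
    CommunityTable,
    FamilyDesign,
    Phylogeny,
    ValidationError,
)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def beta_mntd_profiles(f_j: np.ndarray, f_k: np.ndarray, D: np.ndarray) -> float:
    """betaMNTD between two relative-abundance profiles over a shared
    taxon order, given the patristic distance matrix ``D``.

    ``0.5 * [ sum_i f_ij min_{i' in k} d(i,i') + sum_i f_ik min_{i' in j} d(i,i') ]``
    — each taxon is matched to its nearest taxon *present in the other
    sample* (itself, at distance 0, when shared).
    """
    f_j = np.asarray(f_j, dtype=float)
    f_k = np.asarray(f_k, dtype=float)
    pres_j = np.flatnonzero(f_j > 0)
    pres_k = np.flatnonzero(f_k > 0)
    if pres_j.size == 0 or pres_k.size == 0:
        raise ValidationError("betaMNTD is undefined for an empty sample")
    to_k = D[np.ix_(pres_j, pres_k)].min(axis=1)
    to_j = D[np.ix_(pres_k, pres_j)].min(axis=1)
    return 0.5 * (float(f_j[pres_j] @ to_k) + float(f_k[pres_k] @ to_j))


def _patristic_for_table(table: CommunityTable, phylo: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Patristic matrix aligned to table taxa; returns (D, on_tree_mask).

    Taxa missing from the tree are tolerated here; they become an error
    only if they occur with nonzero abundance in an analysed sample.
    """
    tips = set(phylo.tip_labels)
    on_tree = np.array([t in tips for t in table.taxon_ids])
    present_taxa = [t for t, ok in zip(table.taxon_ids, on_tree) if ok]
    _, D_sub = phylo.patristic_matrix(present_taxa)
    n = table.n_taxa
    D = np.full((n, n), np.nan)
    idx = np.flatnonzero(on_tree)
    D[np.ix_(idx, idx)] = D_sub
    return D, on_tree


def beta_mntd(
    table: CommunityTable, phylo: Phylogeny, pair: tuple[str, str]
) -> float:
    """Observed betaMNTD between two samples of the table."""
    D, on_tree = _patristic_for_table(table, phylo)
    F = table.relative_abundance()
    j, k = (table.sample_index(s) for s in pair)
    for idx in (j, k):
        bad = np.flatnonzero((table.counts[:, idx] > 0) & ~on_tree)
        if len(bad):
            raise ValidationError(
                f"taxon {table.taxon_ids[bad[0]]!r} present in {table.sample_ids[idx]!r} "
                "is not a tip of the tree"
            )
    return beta_mntd_profiles(F[:, j], F[:, k], D)


def _nearest_taxon_matrix(
    D: np.ndarray, present_sets: list[np.ndarray], perm: np.ndarray | None
) -> np.ndarray:
    """Column s = distance of every taxon to its nearest taxon present in
    sample s, under an optional tip-label permutation of ``D``."""
    n = D.shape[0]
    M = np.empty((n, len(present_sets)))
    Dp = D if perm is None else D[perm]  # row i = distances from (relabelled) taxon i
    for s, pres in enumerate(present_sets):
        cols = pres if perm is None else perm[pres]
        M[:, s] = Dp[:, cols].min(axis=1)
    return M


def beta_nti(
    table: CommunityTable,
    phylo: Phylogeny,
    pairs: Sequence[tuple[str, str]],
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """betaNTI for a list of sample pairs under a shared taxa-shuffle null.

    Each null replicate permutes taxon labels across all tree tips (one
    permutation shared by every pair), recomputes betaMNTD, and the
    observed value is z-standardized:
    ``betaNTI = (obs - mean_null) / sd_null``.  Pairs whose null has zero
    spread are flagged with ``betaNTI = NaN``.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    D, on_tree = _patristic_for_table(table, phylo)
    F = table.relative_abundance()

    involved = sorted({s for p in pairs for s in p})
    col = {s: table.sample_index(s) for s in involved}
    for s in involved:
        bad = np.flatnonzero((table.counts[:, col[s]] > 0) & ~on_tree)
        if len(bad):
            raise ValidationError(
                f"taxon {table.taxon_ids[bad[0]]!r} present in {s!r} is not a tip of the tree"
            )

    tree_idx = np.flatnonzero(on_tree)
    Dt = D[np.ix_(tree_idx, tree_idx)]
    remap = -np.ones(table.n_taxa, dtype=int)
    remap[tree_idx] = np.arange(tree_idx.size)

    present_sets = [remap[np.flatnonzero(F[:, col[s]] > 0)] for s in involved]
    weights = [F[:, col[s]][np.flatnonzero(F[:, col[s]] > 0)] for s in involved]
    sample_pos = {s: i for i, s in enumerate(involved)}

    def bmntd_all(perm: np.ndarray | None) -> np.ndarray:
        M = _nearest_taxon_matrix(Dt, present_sets, perm)
        vals = np.empty(len(pairs))
        for q, (a, b) in enumerate(pairs):
            ia, ib = sample_pos[a], sample_pos[b]
            vals[q] = 0.5 * (
                weights[ia] @ M[present_sets[ia], ib]
                + weights[ib] @ M[present_sets[ib], ia]
            )
        return vals

    obs = bmntd_all(None)
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, len(pairs)))
    for r in range(n_null):
        nulls[r] = bmntd_all(rng.permutation(tree_idx.size))
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)

    return pd.DataFrame({
        "sample_i": [a for a, _ in pairs],
        "sample_j": [b for _, b in pairs],
        "beta_mntd": obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "beta_nti": bnti,
        "degenerate_null": null_sd == 0,
        "n_null": n_null,
        "seed": seed,
    })


# ---------------------------------------------------------------------------
# NST
# ---------------------------------------------------------------------------


def _pairwise_similarity(X: np.ndarray, metric: str) -> np.ndarray:
    """Similarity G = 1 - D for all column pairs of a taxa x samples matrix.

    Uses sum(min) = (a + b - |a-b|)/2 and sum(max) = (a + b + |a-b|)/2 so
    both Ruzicka (abundance Jaccard) and Bray-Curtis come from one L1
    pass.
    """
    totals = X.sum(axis=0)
    from scipy.spatial.distance import pdist, squareform

    l1 = squareform(pdist(X.T, metric="cityblock"))
    S = totals[:, None] + totals[None, :]
    if metric == "ruzicka":
        smin = (S - l1) / 2.0
        smax = (S + l1) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            G = np.where(smax > 0, smin / smax, 0.0)
    elif metric == "braycurtis":
        with np.errstate(invalid="ignore", divide="ignore"):
            G = np.where(S > 0, 1.0 - l1 / S, 0.0)
    else:
        raise ValueError("metric must be 'ruzicka' or 'braycurtis'")
    np.fill_diagonal(G, 1.0)
    return G


def nst_pairwise(
    table: CommunityTable,
    n_null: int = 1000,
    seed: int = 0,
    metric: str = "ruzicka",
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and null-expected pairwise similarity over a stratum.

    Returns ``(G_obs, E_null)``, both samples x samples, aligned to
    ``table.sample_ids``.  The PF null fixes each sample's richness,
    draws taxa with probability proportional to occupancy frequency, and
    assigns them the regional mean relative abundances (renormalized).
    """
    F = table.relative_abundance()
    G_obs = _pairwise_similarity(F, metric)

    occupancy = (F > 0).mean(axis=1)
    if occupancy.sum() == 0:
        raise ValidationError("stratum has no taxa present")
    prob = occupancy / occupancy.sum()
    regional = F.mean(axis=1)
    richness = (F > 0).sum(axis=0)
    n_taxa, n_samples = F.shape

    rng = np.random.default_rng(seed)
    E = np.zeros((n_samples, n_samples))
    for _ in range(n_null):
        Xn = np.zeros((n_taxa, n_samples))
        for s in range(n_samples):
            take = rng.choice(n_taxa, size=min(richness[s], n_taxa), replace=False, p=prob)
            ab = regional[take]
            if ab.sum() == 0:
                ab = np.ones(take.size)
            Xn[take, s] = ab / ab.sum()
        E += _pairwise_similarity(Xn, metric)
    E /= n_null
    return G_obs, E


def pair_stochasticity(G: np.ndarray, E: np.ndarray) -> np.ndarray:
    """ST = 1 - SS per pair, from observed and null-expected similarity."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_homog = np.where(E < 1.0, (G - E) / (1.0 - E), 1.0)
        ss_diverge = np.where(E > 0.0, (E - G) / E, 1.0)
    SS = np.where(G >= E, ss_homog, ss_diverge)
    return 1.0 - np.clip(SS, 0.0, 1.0)


def nst(
    table: CommunityTable,
    design: FamilyDesign,
    n_null: int = 1000,
    seed: int = 0,
    metric: str = "ruzicka",
) -> pd.DataFrame:
    """Per-family normalized stochasticity ratio on a stratum table.

    Families reduced to a single present sample are skipped with a
    warning.  ``nst`` is in [0, 1]; ``nst_pct`` is the percentage form in
    which the 50% deterministic/stochastic threshold is usually quoted.
    """
    G, E = nst_pairwise(table, n_null=n_null, seed=seed, metric=metric)
    ST = pair_stochasticity(G, E)
    idx = {s: i for i, s in enumerate(table.sample_ids)}

    rows = []
    for fam in design.families:
        members = [s for s in [fam.mother, *fam.daughters] if s in idx]
        if len(members) < 2:
            warnings.warn(f"family {fam.lineage!r} has fewer than 2 samples, skipped",
                          stacklevel=2)
            continue
        ii = np.array([idx[s] for s in members])
        iu = np.triu_indices(len(ii), k=1)
        pair_idx = (ii[iu[0]], ii[iu[1]])
        st = ST[pair_idx]
        raw = float(st.mean())
        rows.append(dict(
            stratum=str(design.stratum), lineage=fam.lineage, mother=fam.mother,
            n_pairs=len(st),
            observed_dissimilarity=float(1.0 - G[pair_idx].mean()),
            null_dissimilarity=float(1.0 - E[pair_idx].mean()),
            nst=float(np.clip(raw, 0.0, 1.0)),
            nst_pct=100.0 * float(np.clip(raw, 0.0, 1.0)),
            clamped=not (0.0 <= raw <= 1.0),
            metric=metric, null_model="PF", n_null=n_null,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mother-daughter assignment permutation test
# ---------------------------------------------------------------------------


def md_permutation_test(
    statistic_fn: Callable[[str, list[str]], float],
    design: FamilyDesign,
    n_perm: int = 999,
    seed: int = 0,
    statistic_name: str = "statistic",
) -> pd.DataFrame:
    """Z-score each mother's statistic against daughter-reassignment nulls.

    ``statistic_fn(mother_sample_id, daughter_sample_ids)`` is evaluated
    on the true families and on ``n_perm`` random reassignments of the
    stratum's pooled daughters to mothers (family sizes preserved).  With
    few families the number of distinct assignments bounds the attainable
    p-value from below; the +1 correction keeps p in (0, 1].
    """
    if len(design.families) < 2:
        raise ValidationError("need >= 2 families for daughter reassignment")
    mothers = [f.mother for f in design.families]
    sizes = [len(f.daughters) for f in design.families]
    pool = [d for f in design.families for d in f.daughters]

    obs = np.array([statistic_fn(f.mother, f.daughters) for f in design.families])

    rng = np.random.default_rng(seed)
    nulls = np.empty((n_perm, len(mothers)))
    pool_arr = np.array(pool, dtype=object)
    for r in range(n_perm):
        shuffled = pool_arr[rng.permutation(len(pool_arr))]
        start = 0
        for m, (mother, size) in enumerate(zip(mothers, sizes)):
            nulls[r, m] = statistic_fn(mother, list(shuffled[start:start + size]))
            start += size

    # degenerate pair statistics (e.g. betaNTI with a spread-free null) are
    # NaN; drop them from the null rather than poisoning every moment
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.nanmean(nulls, axis=0)
        null_sd = np.nanstd(nulls, axis=0, ddof=1)
    n_valid = (~np.isnan(nulls)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)
    centered_obs = np.abs(obs - null_mean)
    with np.errstate(invalid="ignore"):
        exceed = np.nansum(np.abs(nulls - null_mean) >= centered_obs[None, :] - 1e-12, axis=0)
    p = np.where(
        np.isnan(obs) | (n_valid == 0), np.nan, (1.0 + exceed) / (1.0 + np.maximum(n_valid, 1))
    )

    return pd.DataFrame({
        "mother": mothers,
        "lineage": [f.lineage for f in design.families],
        "stratum": str(design.stratum),
        "statistic": statistic_name,
        "observed": obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "z_score": z,
        "p_value": p,
        "stars": [significance_stars(v) if np.isfinite(v) else "" for v in p],
        "degenerate_null": ~(null_sd > 0),
        "n_perm": n_perm,
        "seed": seed,
    })


def bnti_md_test(
    table: CommunityTable,
    phylo: Phylogeny,
    design: FamilyDesign,
    n_null: int = 999,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """betaNTI for every mother x daughter combination of the stratum plus
    the assignment-permutation Z-test on the per-family mean betaNTI.

    Returns ``(md_pair_results, per_mother_stats)`` where the first frame
    is restricted to the *true* mother-daughter pairs.
    """
    mothers = design.mothers
    daughters = design.daughters
    combos = [(m, d) for m in mothers for d in daughters]
    res = beta_nti(table, phylo, combos, n_null=n_null, seed=seed)
    lut = {(a, b): v for a, b, v in zip(res["sample_i"], res["sample_j"], res["beta_nti"])}

    def family_stat(mother: str, ds: list[str]) -> float:
        vals = [lut[(mother, d)] for d in ds]
        if np.all(np.isnan(vals)):
            return float("nan")
        return float(np.nanmean(vals))

    stats = md_permutation_test(
        family_stat, design, n_perm=n_perm, seed=seed + 1, statistic_name="mean_beta_nti"
    )
    true_pairs = {(m, d) for _, m, d in design.md_pairs()}
    mask = [(a, b) in true_pairs for a, b in zip(res["sample_i"], res["sample_j"])]
    return res[mask].reset_index(drop=True), stats


def nst_md_test(
    table: CommunityTable,
    design: FamilyDesign,
    n_null: int = 1000,
    n_perm: int = 999,
    seed: int = 0,
    metric: str = "ruzicka",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family NST plus the assignment-permutation Z-test.

    The permutation statistic is the mean pair stochasticity over all
    within-family pairs of the (re)assigned family, computed from
    stratum-level observed/null similarities so every reassignment reuses
    the same null expectations.
    """
    G, E = nst_pairwise(table, n_null=n_null, seed=seed, metric=metric)
    ST = pair_stochasticity(G, E)
    idx = {s: i for i, s in enumerate(table.sample_ids)}

    def family_stat(mother: str, ds: list[str]) -> float:
        ii = np.array([idx[s] for s in [mother, *ds]])
        iu = np.triu_indices(len(ii), k=1)
        return float(np.clip(ST[ii[iu[0]], ii[iu[1]]].mean(), 0.0, 1.0))

    fam_nst = nst(table, design, n_null=n_null, seed=seed, metric=metric)
    stats = md_permutation_test(
        family_stat, design, n_perm=n_perm, seed=seed + 1, statistic_name="nst"
    )
    return fam_nst, stats
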