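"""LEfSe-style biomarker discovery at a chosen taxonomic rank.

The procedure mirrors the classic biomarker-discovery recipe: aggregate
counts to a rank (family by default), screen features with a
Kruskal-Wallis test on relative abundances (no multiple-testing
correction, per convention), then score the survivors with a
bootstrap-averaged linear-discriminant effect size on the
million-scaled abundance space, reported as log10.

Simplifications relative to the original tool, by design: a single-level
class factor (no subclass/inner Wilcoxon loop), and the effect size is
the average of the raw and discriminant-weighted class-mean differences
of each feature.  Scores land on the familiar 2-5 log10 scale but are
not numerically identical to the original implementation's.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from vinherit.core_io import CommunityTable, TAXONOMY_RANKS, ValidationError

SCALE = 1e6          # LEfSe works on per-million relative abundances
EFFECT_FLOOR = 1e-10


def aggregate_rank(table: CommunityTable, rank: str) -> CommunityTable:
    """Sum counts over taxa sharing a rank label.

    Taxa with an empty label at ``rank`` are pooled under
    ``"unclassified <parent>"`` where the parent is the nearest non-empty
    higher rank (SILVA-style gaps).
    """
    if table.taxonomy is None:
        raise ValidationError("table has no taxonomy")
    if rank not in table.taxonomy.columns:
        raise ValidationError(f"unknown rank {rank!r}")
    ranks = [r for r in TAXONOMY_RANKS if r in table.taxonomy.columns]
    upto = ranks[: ranks.index(rank)] if rank in ranks else []

    labels = []
    for taxon in table.taxon_ids:
        row = table.taxonomy.loc[taxon]
        label = str(row[rank]) if str(row[rank]) else ""
        if not label:
            parent = ""
            for r in reversed(upto):
                if str(row[r]):
                    parent = str(row[r])
                    break
            label = f"unclassified {parent}".strip()
        labels.append(label)

    frame = pd.DataFrame(table.counts, index=pd.Index(labels, name=rank))
    agg = frame.groupby(level=0, sort=True).sum()
    taxonomy = None
    if upto:
        tax_rows = pd.DataFrame(table.taxonomy[upto].values, index=labels, columns=upto)
        taxonomy = tax_rows.groupby(level=0, sort=True).first()
    return CommunityTable(
        counts=agg.to_numpy(),
        taxon_ids=list(agg.index),
        sample_ids=list(table.sample_ids),
        metadata=table.metadata,
        taxonomy=taxonomy,
        kingdom=table.kingdom,
    )


def _class_labels(table: CommunityTable, class_factor: str | list[str]) -> pd.Series:
    meta = table.metadata.loc[table.sample_ids]
    if isinstance(class_factor, str):
        class_factor = class_factor.split("+")
    missing = [c for c in class_factor if c not in meta.columns]
    if missing:
        raise ValidationError(f"unknown metadata column {missing[0]!r}")
    return meta[class_factor].agg("-".join, axis=1)


def lefse(
    table: CommunityTable,
    class_factor: str | list[str] = "generation+compartment",
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    top_k: int | None = 30,
) -> pd.DataFrame:
    """Rank features by LDA effect size among metadata-defined classes.

    Returns one row per retained feature: the enriched class (largest
    class mean), Kruskal-Wallis p, signed log10 LDA score and the
    per-class mean relative abundances; sorted by |lda_score| descending.
    """
    classes = _class_labels(table, class_factor)
    levels = sorted(classes.unique())
    if len(levels) < 2:
        raise ValidationError("need at least two classes")
    sizes = classes.value_counts()
    if (sizes < 3).any():
        raise ValidationError(f"class {sizes.idxmin()!r} has fewer than 3 samples")

    # canonical sample order so results do not depend on column order
    order = np.argsort(np.asarray(table.sample_ids))
    rel = table.relative_abundance()[:, order]  # taxa x samples
    y = classes.to_numpy()[order]
    feature_ids = np.array(table.taxon_ids)

    # Kruskal-Wallis screen on relative abundances
    kw_p = np.ones(len(feature_ids))
    for i in range(len(feature_ids)):
        groups = [rel[i, y == lev] for lev in levels]
        if np.ptp(rel[i]) == 0:
            kw_p[i] = 1.0                     # constant feature carries no signal
            continue
        kw_p[i] = kruskal(*groups).pvalue
    survivors = np.flatnonzero(kw_p < alpha)
    survivors = survivors[np.argsort(feature_ids[survivors], kind="stable")]
    if survivors.size == 0:
        return pd.DataFrame(
            columns=["taxon", "enriched_class", "kw_p", "lda_score",
                     *[f"mean_{lev}" for lev in levels]]
        )

    X = (rel[survivors] * SCALE).T            # samples x features, per-million
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    effects = np.zeros((n_boot, survivors.size))
    for b in range(n_boot):
        idx = []
        for lev in levels:                    # stratified 2/3 subsample
            members = np.flatnonzero(y == lev)
            take = max(2, int(round(boot_fraction * members.size)))
            idx.extend(rng.choice(members, size=take, replace=False))
        idx = np.asarray(idx)
        Xb, yb = X[idx], y[idx]
        if len(np.unique(yb)) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda = LinearDiscriminantAnalysis(n_components=1)
            try:
                lda.fit(Xb, yb)
            except np.linalg.LinAlgError:
                continue
        w = lda.scalings_[:, 0]
        w = w / (np.abs(w).max() or 1.0)
        means = np.stack([Xb[yb == lev].mean(axis=0) for lev in np.unique(yb)])
        gap = means.max(axis=0) - means.min(axis=0)
        effects[b] = 0.5 * (gap + np.abs(w) * gap)

    mean_eff = effects.mean(axis=0)
    class_means_rel = np.stack([rel[survivors][:, y == lev].mean(axis=1) for lev in levels])
    enriched_idx = class_means_rel.argmax(axis=0)
    scores = np.log10(np.maximum(mean_eff, EFFECT_FLOOR))

    out = pd.DataFrame({
        "taxon": feature_ids[survivors],
        "enriched_class": [levels[k] for k in enriched_idx],
        "kw_p": kw_p[survivors],
        "lda_score": scores,
    })
    for k, lev in enumerate(levels):
        out[f"mean_{lev}"] = class_means_rel[k]
    out = out[np.abs(out["lda_score"]) >= lda_threshold]
    out = out.sort_values("lda_score", key=np.abs, ascending=False, kind="stable")
    if top_k is not None:
        out = out.head(top_k)
    return out.reset_index(drop=True)
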