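"""Mother-daughter resemblance: per-stratum clustering and the
first-quartile pair statistic.

A mother-daughter sample pair counts as "clustered" when its Bray-Curtis
distance falls within the first quartile (Q1, linear interpolation) of
the reference distance distribution.  By default that reference is *all*
pairwise distances within the chateau x tissue x kingdom stratum — the
same pool the per-stratum dendrogram is built from; a pool restricted to
mother-daughter pairs, or a caller-supplied global pool, are available
for sensitivity analysis.  Under the null of no inheritance the
mother-daughter pairs are random draws from the pool, so the long-run
clustered proportion calibrates to 0.25 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.stats import binomtest

from vinherit.core_io import DistanceMatrix, FamilyDesign, ValidationError


@dataclass
class Dendrogram:
    """Agglomerative merge tree over one stratum's samples.

    ``sample_ids`` are in the (lexicographic) leaf order used for the
    linkage, so scipy's lowest-index tie-breaking resolves ties toward
    the lexicographically smallest member id.
    """

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    method: str
    stratum: tuple | None = None

    def cophenetic(self) -> DistanceMatrix:
        from scipy.spatial.distance import squareform

        coph = squareform(cophenet(self.linkage_matrix))
        return DistanceMatrix(list(self.sample_ids), coph, metric=f"cophenetic-{self.method}")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.sample_ids)
        heights = {i: 0.0 for i in range(n)}
        reps = {i: self.sample_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            left = f"{reps[a]}:{h - heights[a]:.6g}"
            right = f"{reps[b]}:{h - heights[b]:.6g}"
            reps[n + k] = f"({left},{right})"
            heights[n + k] = h
        return reps[n + len(self.linkage_matrix) - 1] + ";"


def cluster_stratum(
    dm: DistanceMatrix, method: str = "average", stratum: tuple | None = None
) -> Dendrogram | None:
    """Agglomerative clustering of one stratum (UPGMA by default).

    Samples are sorted lexicographically before linkage so ties resolve
    deterministically toward the smallest member id.  Returns ``None``
    (with a warning) for strata of fewer than 3 samples.
    """
    if len(dm.sample_ids) < 3:
        warnings.warn(f"stratum {stratum}: fewer than 3 samples, no dendrogram", stacklevel=2)
        return None
    ordered = sorted(dm.sample_ids)
    sub = dm.subset(ordered)
    Z = linkage(sub.condensed(), method=method)
    return Dendrogram(sample_ids=ordered, linkage_matrix=Z, method=method, stratum=stratum)


def classify_pairs(
    dm: DistanceMatrix,
    design: FamilyDesign,
    pool: str = "all_pairs",
    reference: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Label each mother-daughter pair clustered iff its distance <= Q1.

    ``pool`` selects the distribution whose first quartile is the
    threshold: ``"all_pairs"`` (every pairwise distance among the
    reference samples, the default) or ``"md_pairs"`` (mother-daughter
    distances only).  ``reference`` defaults to ``dm`` itself; pass a
    wider matrix for a global-pool sensitivity analysis.

    The comparison is inclusive so a degenerate all-equal distribution
    classifies every pair as clustered.
    """
    ref = reference if reference is not None else dm
    known = set(dm.sample_ids)

    pairs = []
    for lineage, mother, daughter in design.md_pairs():
        if mother not in known:
            warnings.warn(f"mother sample {mother!r} missing from distances; "
                          f"family {lineage!r} skipped", stacklevel=2)
            continue
        if daughter not in known:
            warnings.warn(f"daughter sample {daughter!r} missing from distances, skipped",
                          stacklevel=2)
            continue
        pairs.append((lineage, mother, daughter, dm[mother, daughter]))
    if not pairs:
        raise ValidationError("no mother-daughter pair could be evaluated")

    if pool == "all_pairs":
        distribution = ref.condensed()
    elif pool == "md_pairs":
        distribution = np.array([d for *_, d in pairs])
    else:
        raise ValueError("pool must be 'all_pairs' or 'md_pairs'")
    q1 = float(np.percentile(distribution, 25))  # linear interpolation

    rows = [
        dict(stratum=str(design.stratum), lineage=lineage, mother=mother,
             daughter=daughter, bray_curtis=d, q1_threshold=q1, clustered=d <= q1)
        for lineage, mother, daughter, d in pairs
    ]
    return pd.DataFrame(rows)


def proportions(classifications: pd.DataFrame, by: str = "stratum") -> pd.DataFrame:
    """Clustered proportion per stratum with an exact binomial 95% CI."""
    rows = []
    for key, grp in classifications.groupby(by, sort=True):
        k = int(grp["clustered"].sum())
        n = len(grp)
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
        rows.append(dict(stratum=key, clustered=k, total=n, proportion=k / n,
                         ci_low=float(ci.low), ci_high=float(ci.high)))
    return pd.DataFrame(rows)
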