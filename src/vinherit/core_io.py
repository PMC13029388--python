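"""Domain types and readers/writers shared by every analysis stage.

The central object is :class:`CommunityTable`: a taxa x samples count
matrix with aligned per-sample metadata and per-taxon ranked taxonomy.
Bacterial (16S) and fungal (18S) tables are always kept separate; no
operation mixes kingdoms.

Counts orientation is fixed as taxa rows x sample columns with the first
column holding taxon ids.  A transposed input is auto-detected only when
its row labels match the metadata sample ids — silent transposition is the
classic microbiome table bug, so anything ambiguous is a hard error.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

METADATA_COLUMNS = ("sample_id", "chateau", "compartment", "generation", "lineage", "vine_id")
TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
COMPARTMENTS = ("leaf", "root", "soil")
GENERATIONS = ("PM", "PF")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Taxa x samples count matrix with aligned metadata and taxonomy.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_taxa, n_samples)``.
    taxon_ids, sample_ids
        Ordered unique labels for rows / columns.
    metadata
        One record per sample, indexed by ``sample_id``; required columns
        are ``chateau``, ``compartment``, ``generation`` (PM = mother,
        PF = daughter), ``lineage`` and ``vine_id``.
    taxonomy
        Ranked lineage per taxon (kingdom..genus), indexed by taxon id;
        missing ranks are empty strings.
    kingdom
        Marker kingdom of the whole table ("bacteria" or "fungi").
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    kingdom: str = "bacteria"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n_taxa, n_samples = self.counts.shape
        if n_taxa != len(self.taxon_ids):
            raise ValidationError(
                f"counts has {n_taxa} rows but {len(self.taxon_ids)} taxon ids"
            )
        if n_samples != len(self.sample_ids):
            raise ValidationError(
                f"counts has {n_samples} columns but {len(self.sample_ids)} sample ids"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise ValidationError(f"duplicate {name} id: {dupes[0]!r}")
        neg = np.argwhere(self.counts < 0)
        if len(neg):
            raise ValidationError(
                f"negative count for taxon {self.taxon_ids[neg[0][0]]!r} "
                f"in sample {self.sample_ids[neg[0][1]]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.metadata.index]
        if missing:
            raise ValidationError(f"sample {missing[0]!r} has no metadata record")

    # -- accessors ---------------------------------------------------------
    def zero_taxa(self) -> list[str]:
        """Taxa with zero total count (retained, but flagged by readers)."""
        idx = np.flatnonzero(self.counts.sum(axis=1) == 0)
        return [self.taxon_ids[i] for i in idx]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized abundances f_{i,j}; zero-sum samples are an error."""
        totals = self.counts.sum(axis=0).astype(float)
        zero = np.flatnonzero(totals == 0)
        if len(zero):
            raise ValidationError(f"sample {self.sample_ids[zero[0]]!r} has zero total count")
        return self.counts / totals

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CommunityTable(
            counts=self.counts[:, idx],
            taxon_ids=list(self.taxon_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            metadata=self.metadata,
            taxonomy=self.taxonomy,
            kingdom=self.kingdom,
        )

    def iter_strata(
        self, by: Sequence[str] = ("chateau", "compartment")
    ) -> Iterator[tuple[tuple, "CommunityTable"]]:
        """Yield ``(stratum_key, sub-table)`` per combination of metadata factors."""
        meta = self.metadata.loc[self.sample_ids]
        for key, grp in meta.groupby(list(by), observed=True, sort=True):
            yield key, self.subset_samples(list(grp.index))

    # -- io ----------------------------------------------------------------
    def write(self, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
        """Write counts/metadata/taxonomy TSVs; returns path per artefact."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        counts = pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)
        counts.index.name = "taxon_id"
        paths["counts"] = out_dir / f"{prefix}counts.tsv"
        counts.to_csv(paths["counts"], sep="\t")
        meta = self.metadata.loc[self.sample_ids].copy()
        meta.index.name = "sample_id"
        paths["metadata"] = out_dir / f"{prefix}metadata.tsv"
        meta.to_csv(paths["metadata"], sep="\t")
        if self.taxonomy is not None:
            tax = self.taxonomy.loc[self.taxon_ids].copy()
            tax.index.name = "taxon_id"
            paths["taxonomy"] = out_dir / f"{prefix}taxonomy.tsv"
            tax.to_csv(paths["taxonomy"], sep="\t")
        return paths


@dataclass
class Phylogeny:
    """Rooted tree over taxa with non-negative branch lengths.

    Wraps a :class:`dendropy.Tree`; tips must be labelled by taxon ids of
    the matching kingdom's :class:`CommunityTable`.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValidationError("tree contains an unlabelled tip")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError("tree contains a negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def patristic_matrix(self, taxon_order: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Pairwise tip-to-tip path-length distances.

        Returns ``(labels, D)`` with ``D`` symmetric, zero-diagonal, ordered
        by ``taxon_order`` when given (all of which must be tips).
        """
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = self.tip_labels
        by_label = {t.label: t for t in self.tree.taxon_namespace if t.label in set(labels)}
        if taxon_order is not None:
            missing = [t for t in taxon_order if t not in by_label]
            if missing:
                raise ValidationError(f"taxon {missing[0]!r} is not a tip of the tree")
            labels = list(taxon_order)
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(by_label[labels[i]], by_label[labels[j]])
                D[i, j] = D[j, i] = d
        return labels, D

    def prune_to(self, taxa: Iterable[str]) -> "Phylogeny":
        keep = set(taxa)
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels([t for t in self.tip_labels if t in keep])
        return Phylogeny(tree=tree)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among samples."""

    sample_ids: list[str]
    data: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample ids")
        if np.max(np.abs(np.diag(self.data))) > 1e-12:
            raise ValidationError("distance matrix diagonal must be zero")
        if np.max(np.abs(self.data - self.data.T)) > 1e-12:
            raise ValidationError("distance matrix must be symmetric")
        if self.metric == "braycurtis" and (self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12):
            raise ValidationError("Bray-Curtis entries must lie in [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.data[i, j])

    def subset(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.data[np.ix_(idx, idx)], self.metric)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.data[iu]


@dataclass
class Family:
    """One mother vine plus her sampled clonal daughters (sample ids)."""

    lineage: str
    mother: str
    daughters: list[str]

    @property
    def size(self) -> int:
        return 1 + len(self.daughters)


@dataclass
class FamilyDesign:
    """Families within one chateau x compartment x kingdom stratum.

    The family is the exchangeability unit of every permutation test:
    daughters may be reassigned among mothers of the same stratum, never
    across strata.
    """

    stratum: tuple
    families: list[Family] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for fam in self.families:
            for d in fam.daughters:
                if d in seen:
                    raise ValidationError(
                        f"daughter sample {d!r} appears in families {seen[d]!r} and {fam.lineage!r}"
                    )
                seen[d] = fam.lineage

    @property
    def mothers(self) -> list[str]:
        return [f.mother for f in self.families]

    @property
    def daughters(self) -> list[str]:
        return [d for f in self.families for d in f.daughters]

    def md_pairs(self) -> list[tuple[str, str, str]]:
        """All (lineage, mother, daughter) sample-id pairs."""
        return [(f.lineage, f.mother, d) for f in self.families for d in f.daughters]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_community(
    counts_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path | None = None,
    kingdom: str = "bacteria",
    column_map: Mapping[str, str] | None = None,
) -> CommunityTable:
    """Read a counts/metadata/taxonomy TSV triple into a validated table.

    ``column_map`` maps canonical metadata column names to the names used in
    the file (e.g. ``{"chateau": "Site"}``), accommodating deposited tables
    whose headers differ from ours.
    """
    counts_df = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = _apply_column_map(pd.read_csv(metadata_path, sep="\t", dtype=str), column_map)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata is missing required column {missing_cols[0]!r}")
    meta = meta.set_index("sample_id")

    # orientation check: columns must be samples
    cols_in_meta = counts_df.columns.isin(meta.index)
    if not cols_in_meta.all():
        rows_in_meta = counts_df.index.isin(meta.index)
        if rows_in_meta.all():
            counts_df = counts_df.T  # transposed input, sample rows detected
        else:
            bad = counts_df.columns[~cols_in_meta][0]
            raise ValidationError(f"sample {bad!r} in counts has no metadata record")

    if not np.issubdtype(counts_df.values.dtype, np.number):
        raise ValidationError("counts table contains non-numeric values")
    values = counts_df.values
    if not np.allclose(values, np.round(values)):
        raise ValidationError("counts table must contain integer counts")

    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
        taxonomy = _apply_column_map(taxonomy, column_map).set_index("taxon_id")
        taxonomy = taxonomy.reindex(counts_df.index, fill_value="")

    table = CommunityTable(
        counts=np.round(values).astype(np.int64),
        taxon_ids=list(counts_df.index.astype(str)),
        sample_ids=list(counts_df.columns.astype(str)),
        metadata=meta,
        taxonomy=taxonomy,
        kingdom=kingdom,
    )
    zero = table.zero_taxa()
    if zero:
        warnings.warn(
            f"{len(zero)} all-zero taxon rows retained (e.g. {zero[0]!r})", stacklevel=2
        )
    return table


def read_tree(newick_path: str | Path, table: CommunityTable | None = None) -> Phylogeny:
    """Read a Newick tree, pruning it to the taxa present in ``table``.

    Tips absent from the table are dropped with a warning.  A table taxon
    missing from the tree is *not* an error here — phylogenetic stages check
    coverage themselves when they run.
    """
    tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
    phylo = Phylogeny(tree=tree)
    if table is not None:
        extra = sorted(set(phylo.tip_labels) - set(table.taxon_ids))
        if extra:
            warnings.warn(f"pruning {len(extra)} tips absent from table: {extra[:5]}", stacklevel=2)
            phylo = phylo.prune_to(set(table.taxon_ids))
        lost = sorted(set(table.taxon_ids) - set(phylo.tip_labels))
        if lost:
            warnings.warn(
                f"{len(lost)} table taxa have no tip in the tree (e.g. {lost[0]!r}); "
                "betaMNTD will fail if they occur in analysed samples",
                stacklevel=2,
            )
    return phylo


def build_family_design(table: CommunityTable, stratum: tuple | None = None) -> FamilyDesign:
    """Map each mother (PM) sample to her daughters' (PF) samples by lineage.

    Daughters whose lineage matches no mother in the stratum are excluded
    with a warning; two mothers sharing a lineage within one stratum is an
    error (the mapping would be ambiguous).
    """
    meta = table.metadata.loc[table.sample_ids]
    pm = meta[meta["generation"] == "PM"]
    pf = meta[meta["generation"] == "PF"]
    if pm.empty or pf.empty:
        raise ValidationError("stratum must contain at least one PM and one PF sample")

    mothers: dict[str, str] = {}
    for sample_id, row in pm.iterrows():
        lineage = row["lineage"]
        if lineage in mothers:
            raise ValidationError(
                f"ambiguous mother: lineage {lineage!r} has PM samples "
                f"{mothers[lineage]!r} and {sample_id!r}"
            )
        mothers[lineage] = sample_id

    daughters: dict[str, list[str]] = {lin: [] for lin in mothers}
    orphans = []
    for sample_id, row in pf.iterrows():
        lineage = row["lineage"]
        if lineage in daughters:
            daughters[lineage].append(sample_id)
        else:
            orphans.append(sample_id)
    if orphans:
        warnings.warn(
            f"{len(orphans)} PF samples have no matching mother and were excluded "
            f"(e.g. {orphans[0]!r})",
            stacklevel=2,
        )

    families = [
        Family(lineage=lin, mother=mothers[lin], daughters=sorted(daughters[lin]))
        for lin in sorted(mothers)
        if daughters[lin]
    ]
    if stratum is None:
        chx = sorted(meta["chateau"].unique())
        cmp_ = sorted(meta["compartment"].unique())
        stratum = (chx[0] if len(chx) == 1 else tuple(chx),
                   cmp_[0] if len(cmp_) == 1 else tuple(cmp_),
                   table.kingdom)
    return FamilyDesign(stratum=stratum, families=families)


def write_manifest(path: str | Path, seed: int | None, parameters: Mapping | None = None) -> Path:
    """Write the JSON run-manifest (seed, parameters, package versions)."""
    import scipy
    import sklearn

    from vinherit import __version__

    manifest = {
        "seed": seed,
        "parameters": dict(parameters or {}),
        "versions": {
            "vinherit": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "dendropy": dendropy.__version__,
        },
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
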