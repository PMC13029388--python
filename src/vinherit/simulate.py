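"""Lineage-structured synthetic communities with known ground truth.

The generator emulates a multi-site mass-selection design: at each site
("chateau") a set of old mother vines (generation PM) has clonal daughter
vines (PF), and each vine is sampled in one or more compartments (leaf,
root, optionally soil).  Community assembly follows a Gaussian
environmental-filtering model on a simulated phylogeny:

* a Yule (pure-birth) tree over ``n_taxa`` taxa;
* per-taxon environmental optima evolved by Brownian motion on that tree,
  so close relatives have similar optima (the phylogenetic signal that
  betaNTI-style analyses assume);
* per-sample scalar environment built additively from site, compartment
  and generation shifts plus sample-level noise;
* expected relative abundances p_i proportional to
  ``base_i * exp(-(optimum_i - env)^2 / (2 sigma_sel^2))`` with lognormal
  base abundances shared across samples;
* a tunable vertical-transmission fraction ``v``: a daughter's expected
  composition is ``v * p_mother_realized + (1 - v) * p_env``, mixing the
  mother's *realized* (sampled) composition with the daughter's own
  environmental pool;
* multinomial read sampling at Poisson-distributed library sizes.

``sigma_sel`` controls determinism: small values mean strong selection
(deterministic assembly, amplifying environmental differences), huge
values (>= 1e9) switch filtering off entirely (neutral regime).

Every sample gets its own RNG stream derived by hashing
``(seed, sample_id)``, so adding samples never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from vinherit.core_io import CommunityTable, Family, FamilyDesign, Phylogeny

# neutral-regime sentinel: selection switched off at or above this width
NEUTRAL_SIGMA = 1e9

_COMPARTMENT_SHIFT = {"leaf": 1.0, "root": -1.0, "soil": -0.5}
_GENERATION_SHIFT = {"PM": 0.5, "PF": -0.5}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``site_structure`` gives ``(n_families, daughters_per_mother)`` per
    site; when ``None`` it is built from ``n_sites`` x
    ``families_per_site`` x ``daughters_per_mother``.
    """

    n_taxa: int = 150
    n_sites: int = 4
    compartments: tuple[str, ...] = ("leaf", "root")
    families_per_site: int = 8
    daughters_per_mother: int = 3
    depth: int = 5000
    v: float = 0.3                      # vertical-transmission fraction
    sigma_sel: float = 1.5              # filtering width; larger = weaker selection
    site_effect: float = 1.2
    compartment_effect: float = 3.0
    generation_effect: float = 0.15
    env_noise: float = 0.4              # sd of per-sample environmental noise
    bm_rate: float = 1.0                # Brownian-motion rate for optima
    seed: int = 0
    kingdom: str = "bacteria"
    site_structure: list[tuple[int, int]] | None = None
    site_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0.0 <= self.v <= 1.0:
            raise ValueError("v must lie in [0, 1]")
        if self.sigma_sel <= 0:
            raise ValueError("sigma_sel must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for name in ("n_sites", "families_per_site", "daughters_per_mother"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        unknown = set(self.compartments) - set(_COMPARTMENT_SHIFT)
        if unknown:
            raise ValueError(f"unknown compartment {sorted(unknown)[0]!r}")

    def resolved_structure(self) -> list[tuple[str, int, int]]:
        """Per-site ``(site_name, n_families, daughters_per_mother)``."""
        if self.site_structure is not None:
            struct = list(self.site_structure)
        else:
            struct = [(self.families_per_site, self.daughters_per_mother)] * self.n_sites
        names = self.site_names or [f"Site{i + 1}" for i in range(len(struct))]
        if len(names) != len(struct):
            raise ValueError("site_names length must match site_structure")
        return [(names[i], nf, dpm) for i, (nf, dpm) in enumerate(struct)]


def paper_preset(**overrides) -> SimulationConfig:
    """Four-estate design: 15 mothers x 5 daughters, 10 x 3, 12 x 3 and
    10 x 1 — 47 mothers and 151 daughters per compartment per kingdom."""
    cfg = SimulationConfig(
        n_sites=4,
        site_structure=[(15, 5), (10, 3), (12, 3), (10, 1)],
        site_names=["Latour", "Lafite", "LeovilleLasCases", "Palmer"],
        n_taxa=150,
        compartments=("leaf", "root"),
        depth=5000,
    )
    return replace(cfg, **overrides)


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated table."""

    optima: pd.Series                   # per-taxon environmental optimum
    environment: pd.Series              # per-sample realized environment
    expected_abundance: pd.DataFrame    # taxa x samples expected rel. abundances


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Deterministic stream per (seed, sample_id); stable across runs."""
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def simulate_tree(n_taxa: int, seed: int) -> Phylogeny:
    """Ultrametric Yule (pure-birth, rate 1) tree with tips T0001..Tn."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng([seed, zlib.crc32(b"tree")])
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node.birth_time = 0.0
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(int(rng.integers(len(active))))
        parent.split_time = t
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = t
            active.append(child)
    present = t + rng.exponential(1.0 / n_taxa)  # extend tip branches past the last split
    for k, leaf in enumerate(sorted(active, key=lambda nd: nd.birth_time)):
        leaf.taxon = ns.new_taxon(f"T{k + 1:04d}")
    for node in tree.preorder_node_iter():
        end = node.split_time if hasattr(node, "split_time") else present
        node.edge.length = end - node.birth_time
    return Phylogeny(tree=tree)


def evolve_optima(phylo: Phylogeny, bm_rate: float, seed: int) -> pd.Series:
    """Brownian-motion trait values per tip, root value 0.

    Each branch contributes an independent Normal(0, bm_rate * length)
    increment, so tips sharing ancestry are correlated with covariance
    equal to ``bm_rate`` times their shared path length from the root.
    """
    rng = np.random.default_rng([seed, zlib.crc32(b"optima")])
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in phylo.tree.preorder_node_iter():
        if node.parent_node is None:
            val = 0.0
        else:
            length = node.edge.length or 0.0
            val = values[id(node.parent_node)] + rng.normal(0.0, np.sqrt(bm_rate * length))
        values[id(node)] = val
        if node.is_leaf():
            out[node.taxon.label] = val
    return pd.Series(out).sort_index()


def filtering_weights(
    optima: np.ndarray, env: float, sigma_sel: float, base_abundance: np.ndarray
) -> np.ndarray:
    """Expected relative abundances under Gaussian environmental filtering.

    Computed in log space so strong selection never underflows to an
    all-zero vector.
    """
    base = np.asarray(base_abundance, dtype=float)
    if np.all(base <= 0):
        raise ValueError("base abundances are all zero")
    logw = np.where(base > 0, np.log(np.where(base > 0, base, 1.0)), -np.inf)
    if sigma_sel < NEUTRAL_SIGMA:
        logw = logw - (np.asarray(optima) - env) ** 2 / (2.0 * sigma_sel**2)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def assemble_sample(
    optima: np.ndarray,
    env: float,
    sigma_sel: float,
    base_abundance: np.ndarray,
    depth: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw one community: multinomial(depth, filtered expected abundances)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    p = filtering_weights(optima, env, sigma_sel, base_abundance)
    return rng.multinomial(depth, p)


def _synthetic_taxonomy(phylo: Phylogeny, kingdom: str, taxa_per_family: int = 5) -> pd.DataFrame:
    """Ranked taxonomy whose families are contiguous clades of the tree."""
    leaf_order = [leaf.taxon.label for leaf in phylo.tree.leaf_node_iter()]
    rows = {}
    for i, taxon in enumerate(leaf_order):
        fam = i // taxa_per_family
        rows[taxon] = {
            "kingdom": kingdom,
            "phylum": f"Phy{fam // 16:02d}",
            "class": f"Cls{fam // 8:02d}",
            "order": f"Ord{fam // 4:03d}",
            "family": f"Fam{fam:03d}",
            "genus": f"Gen{i // 2:03d}",
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def simulate_study(
    config: SimulationConfig,
) -> tuple[CommunityTable, Phylogeny, list[FamilyDesign], SimulationTruth]:
    """Generate the full lineage-structured study for one kingdom.

    Every (vine, compartment) combination yields one sample.  Mothers
    assemble from their environment; daughters mix the mother's realized
    composition (fraction ``v``, leaf and root only — soil is not plant
    tissue and assembles purely environmentally) with their own
    environmental pool.  Returns the table, the phylogeny, one
    :class:`FamilyDesign` per site x compartment stratum, and the ground
    truth.
    """
    cfg = config
    phylo = simulate_tree(cfg.n_taxa, cfg.seed)
    optima = evolve_optima(phylo, cfg.bm_rate, cfg.seed)
    taxon_ids = list(optima.index)
    opt = optima.values

    rng_global = np.random.default_rng([cfg.seed, zlib.crc32(b"base")])
    base = rng_global.lognormal(0.0, 1.0, size=cfg.n_taxa)

    structure = cfg.resolved_structure()
    site_positions = np.linspace(-1.0, 1.0, len(structure)) if len(structure) > 1 else np.array([0.0])

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    counts_cols: list[np.ndarray] = []
    env_by_sample: dict[str, float] = {}
    expected: dict[str, np.ndarray] = {}
    designs: list[FamilyDesign] = []

    def make_sample(sid: str, env_mean: float, maternal_p: np.ndarray | None, v: float):
        rng = _sample_rng(cfg.seed, sid)
        env = env_mean + rng.normal(0.0, cfg.env_noise)
        p_env = filtering_weights(opt, env, cfg.sigma_sel, base)
        p = v * maternal_p + (1.0 - v) * p_env if maternal_p is not None else p_env
        depth = max(1, int(rng.poisson(cfg.depth)))
        counts = rng.multinomial(depth, p)
        env_by_sample[sid] = env
        expected[sid] = p
        counts_cols.append(counts)
        sample_ids.append(sid)
        return counts

    for s_idx, (site, n_fam, dpm) in enumerate(structure):
        site_env = cfg.site_effect * site_positions[s_idx]
        for comp in cfg.compartments:
            comp_env = cfg.compartment_effect * _COMPARTMENT_SHIFT[comp]
            families: list[Family] = []
            for f in range(n_fam):
                lineage = f"{site[:2].upper()}{f + 1:02d}"
                mother_vine = f"{site}-{lineage}-PM"
                mid = f"{site}.{lineage}.PM.{comp}"
                env_mean = site_env + comp_env + cfg.generation_effect * _GENERATION_SHIFT["PM"]
                mother_counts = make_sample(mid, env_mean, None, 0.0)
                meta_rows.append(
                    dict(sample_id=mid, chateau=site, compartment=comp, generation="PM",
                         lineage=lineage, vine_id=mother_vine, kingdom=cfg.kingdom)
                )
                mother_realized = mother_counts / mother_counts.sum()
                daughters = []
                for d in range(dpm):
                    did = f"{site}.{lineage}.PF{d + 1}.{comp}"
                    env_mean_d = site_env + comp_env + cfg.generation_effect * _GENERATION_SHIFT["PF"]
                    maternal = mother_realized if comp != "soil" else None
                    make_sample(did, env_mean_d, maternal, cfg.v if comp != "soil" else 0.0)
                    meta_rows.append(
                        dict(sample_id=did, chateau=site, compartment=comp, generation="PF",
                             lineage=lineage, vine_id=f"{site}-{lineage}-PF{d + 1}",
                             kingdom=cfg.kingdom)
                    )
                    daughters.append(did)
                families.append(Family(lineage=lineage, mother=mid, daughters=daughters))
            designs.append(FamilyDesign(stratum=(site, comp, cfg.kingdom), families=families))

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = CommunityTable(
        counts=np.column_stack(counts_cols).astype(np.int64),
        taxon_ids=taxon_ids,
        sample_ids=sample_ids,
        metadata=metadata,
        taxonomy=_synthetic_taxonomy(phylo, cfg.kingdom),
        kingdom=cfg.kingdom,
    )
    truth = SimulationTruth(
        optima=optima,
        environment=pd.Series(env_by_sample),
        expected_abundance=pd.DataFrame(
            {sid: expected[sid] for sid in sample_ids}, index=taxon_ids
        ),
    )
    return table, phylo, designs, truth
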