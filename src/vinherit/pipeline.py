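"""One-config orchestration of the H1 -> H2 -> H3 analysis flow.

``run_all`` consumes a :class:`RunConfig` (usually parsed from YAML),
either simulating a study or reading counts/metadata/taxonomy/tree
files, and writes figure-ready TSVs plus a JSON manifest:

    alpha.tsv, alpha_tests.tsv, ordination.tsv, permanova.tsv,
    lefse.tsv, pairs.tsv, proportions.tsv, dendrograms.nwk,
    bnti_pairs.tsv, nst_families.tsv, zscores.tsv, manifest.json

Every stage draws its seed deterministically from the global seed and
the stage name, so reruns are byte-identical and a stage rerun in
isolation matches the full-pipeline output.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from vinherit import alpha as alpha_mod
from vinherit import assembly as asm
from vinherit import beta as beta_mod
from vinherit import lefse as lefse_mod
from vinherit import lineage as lineage_mod
from vinherit.core_io import (
    CommunityTable,
    Phylogeny,
    build_family_design,
    read_community,
    read_tree,
    write_manifest,
)
from vinherit.simulate import SimulationConfig, paper_preset, simulate_study

log = logging.getLogger("vinherit")


class StageError(RuntimeError):
    """A stage failed; the message carries the stage tag."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    out_dir: str = "vinherit_out"
    # input: either simulation settings or file paths per kingdom
    simulate: dict[str, Any] | None = None            # SimulationConfig fields
    preset: str | None = None                         # "paper" installs the 4-estate design
    kingdoms: tuple[str, ...] = ("bacteria", "fungi")
    inputs: dict[str, dict[str, str]] | None = None   # kingdom -> {counts,metadata,taxonomy,tree}
    # stage switches and parameters
    stages: tuple[str, ...] = ("alpha", "ordination", "permanova", "lefse", "lineage", "assembly")
    permanova_factors: tuple[str, ...] = ("compartment", "chateau", "generation")
    permanova_mode: str = "marginal"
    n_perm: int = 999
    lefse_rank: str = "family"
    lefse_class: str = "generation+compartment"
    lefse_top: int = 30
    linkage: str = "average"
    quartile_pool: str = "all_pairs"
    n_null: int = 199
    nst_metric: str = "ruzicka"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key {sorted(unknown)[0]!r}")
        for key in ("kingdoms", "stages", "permanova_factors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 1000003 + zlib.crc32(stage.encode())) % 2**31)


def _load_tables(cfg: RunConfig):
    """Yield (kingdom, table, phylogeny|None, designs) per kingdom."""
    if cfg.inputs:
        for kingdom, paths in cfg.inputs.items():
            table = read_community(
                paths["counts"], paths["metadata"], paths.get("taxonomy"), kingdom=kingdom
            )
            phylo = read_tree(paths["tree"], table) if paths.get("tree") else None
            designs = []
            for key, sub in table.iter_strata(("chateau", "compartment")):
                try:
                    designs.append(build_family_design(sub, stratum=(*key, kingdom)))
                except Exception as exc:  # sparse stratum: log and move on
                    log.warning("stratum %s: no family design (%s)", key, exc)
            yield kingdom, table, phylo, designs
        return
    for i, kingdom in enumerate(cfg.kingdoms):
        params = dict(cfg.simulate or {})
        params.setdefault("seed", cfg.seed + i)
        params["kingdom"] = kingdom
        sim_cfg = paper_preset(**params) if cfg.preset == "paper" else SimulationConfig(**params)
        table, phylo, designs, _ = simulate_study(sim_cfg)
        yield kingdom, table, phylo, designs


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Run every enabled stage and write the output TSVs + manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected: dict[str, list[pd.DataFrame]] = {}
    newicks: list[str] = []

    def add(name: str, frame: pd.DataFrame, kingdom: str) -> None:
        frame = frame.copy()
        frame.insert(0, "kingdom", kingdom)
        collected.setdefault(name, []).append(frame)

    for kingdom, table, phylo, designs in _load_tables(cfg):
        log.info("kingdom %s: %d taxa x %d samples", kingdom, table.n_taxa, table.n_samples)
        try:
            if "alpha" in cfg.stages:
                panel = alpha_mod.alpha_panel(table)
                add("alpha", panel.reset_index(), kingdom)
                add("alpha_tests", alpha_mod.compare_generations(panel, table.metadata), kingdom)
            dm = beta_mod.bray_curtis(table)
            if "ordination" in cfg.stages:
                ordn = beta_mod.pcoa(dm)
                coords = ordn.to_frame().iloc[:, :4].reset_index(names="sample_id")
                for i, prop in enumerate(ordn.proportion_explained[:4]):
                    coords[f"prop_axis{i + 1}"] = prop
                add("ordination", coords, kingdom)
            if "permanova" in cfg.stages:
                add("permanova", beta_mod.permanova(
                    dm, table.metadata, list(cfg.permanova_factors),
                    n_perm=cfg.n_perm, seed=cfg.stage_seed("permanova"),
                    mode=cfg.permanova_mode), kingdom)
            if "lefse" in cfg.stages:
                ranked = lefse_mod.aggregate_rank(table, cfg.lefse_rank)
                add("lefse", lefse_mod.lefse(
                    ranked, cfg.lefse_class, seed=cfg.stage_seed("lefse"),
                    top_k=cfg.lefse_top), kingdom)
        except Exception as exc:
            raise StageError(f"[H1/{kingdom}] {exc}") from exc

        if "lineage" in cfg.stages:
            try:
                for design in designs:
                    members = set(table.sample_ids) & set(
                        table.metadata.index[
                            (table.metadata["chateau"] == design.stratum[0])
                            & (table.metadata["compartment"] == design.stratum[1])
                        ]
                    )
                    sub = table.subset_samples(sorted(members))
                    dms = beta_mod.bray_curtis(sub)
                    dend = lineage_mod.cluster_stratum(dms, method=cfg.linkage,
                                                       stratum=design.stratum)
                    if dend is not None:
                        newicks.append(f"{design.stratum}\t{dend.to_newick()}")
                    pairs = lineage_mod.classify_pairs(dms, design, pool=cfg.quartile_pool)
                    add("pairs", pairs, kingdom)
                    add("proportions", lineage_mod.proportions(pairs), kingdom)
            except Exception as exc:
                raise StageError(f"[H2/{kingdom}] {exc}") from exc

        if "assembly" in cfg.stages:
            if phylo is None:
                raise StageError(f"[H3/{kingdom}] assembly stage requires a tree")
            try:
                for design in designs:
                    stratum_samples = sorted(
                        {design.families[0].mother}
                        | set(design.mothers) | set(design.daughters)
                    )
                    sub = table.subset_samples(stratum_samples)
                    bnti_pairs, bnti_z = asm.bnti_md_test(
                        sub, phylo, design, n_null=cfg.n_null,
                        n_perm=cfg.n_perm, seed=cfg.stage_seed("bnti"))
                    fam_nst, nst_z = asm.nst_md_test(
                        sub, design, n_null=cfg.n_null, n_perm=cfg.n_perm,
                        seed=cfg.stage_seed("nst"), metric=cfg.nst_metric)
                    bnti_pairs.insert(0, "stratum", str(design.stratum))
                    add("bnti_pairs", bnti_pairs, kingdom)
                    add("nst_families", fam_nst, kingdom)
                    add("zscores", pd.concat([bnti_z, nst_z], ignore_index=True), kingdom)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[H3/{kingdom}] {exc}") from exc

    paths: dict[str, Path] = {}
    for name, frames in collected.items():
        paths[name] = out / f"{name}.tsv"
        pd.concat(frames, ignore_index=True).to_csv(
            paths[name], sep="\t", index=False, float_format="%.10g")
    if newicks:
        paths["dendrograms"] = out / "dendrograms.nwk"
        paths["dendrograms"].write_text("\n".join(newicks) + "\n")
    paths["manifest"] = write_manifest(
        out / "manifest.json", cfg.seed,
        {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in cfg.__dict__.items() if k != "inputs"},
    )
    return paths
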