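"""Shared fixtures: a small simulated study and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from vinherit.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Two sites x two compartments, 4 families of 3 daughters each."""
    cfg = SimulationConfig(
        n_taxa=40, n_sites=2, families_per_site=4, daughters_per_mother=3,
        depth=2000, seed=11,
    )
    return simulate_study(cfg)


def brute_force_beta_mntd(f_j, f_k, D) -> float:
    """Literal nearest-taxon enumeration, independent of the package path."""
    A = [i for i, v in enumerate(f_j) if v > 0]
    B = [i for i, v in enumerate(f_k) if v > 0]
    s1 = sum(f_j[i] * min(D[i][jj] for jj in B) for i in A)
    s2 = sum(f_k[j] * min(D[j][ii] for ii in A) for j in B)
    return 0.5 * (s1 + s2)


def exact_ranksum_p(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(x)
    obs = abs(ranks[:n1].sum() - n1 * (len(pooled) + 1) / 2.0)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        stat = abs(ranks[list(combo)].sum() - n1 * (len(pooled) + 1) / 2.0)
        count += stat >= obs - 1e-12
        total += 1
    return count / total


def random_phylogeny_matrix(rng: np.random.Generator, n_taxa: int) -> np.ndarray:
    """Random ultrametric-ish patristic matrix built from a random tree."""
    from vinherit.simulate import simulate_tree

    phylo = simulate_tree(n_taxa, int(rng.integers(2**31 - 1)))
    _, D = phylo.patristic_matrix([f"T{i + 1:04d}" for i in range(n_taxa)])
    return D
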