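import numpy as np
import pandas as pd
import pytest

from layerqtl.data import Pedigree, UNKNOWN_PARENT
from layerqtl.simulate import QTLSpec, SimConfig, TraitSpec, simulate_dataset


def small_sim_config(**overrides) -> SimConfig:
    """A fast one-trait daughter-design configuration for tests."""
    base = dict(
        n_sires=120,
        n_daughters_per_sire=24,
        cage_size=12,
        n_markers_per_chromosome={"1": 30, "2": 25, "3": 20},
        traits=[TraitSpec("HU", "quality", 73.0, sigma2_g=0.3, sigma2_e=0.7)],
        n_hatches=1,
        seed=1234,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated dataset shared by read-only tests."""
    return simulate_dataset(small_sim_config())


def random_pedigree(rng: np.random.Generator, n: int = 20,
                    p_parent: float = 0.7) -> Pedigree:
    """Random valid pedigree: each individual may pick earlier parents."""
    ids = [f"I{i}" for i in range(n)]
    sires, dams = [], []
    for i in range(n):
        pool = ids[:i]
        s = rng.choice(pool) if pool and rng.random() < p_parent else UNKNOWN_PARENT
        remaining = [x for x in pool if x != s]
        d = rng.choice(remaining) if remaining and rng.random() < p_parent \
            else UNKNOWN_PARENT
        sires.append(s)
        dams.append(d)
    return Pedigree(pd.DataFrame({"id": ids, "sire": sires, "dam": dams}))


def gene_dropping_A(ped: Pedigree, n_drops: int = 100_000,
                    seed: int = 0) -> np.ndarray:
    """Monte-Carlo oracle for the additive relationship matrix.

    Unique founder alleles are dropped through the pedigree; the
    relationship a_ij is estimated as twice the probability that one
    allele drawn at random from i is identical by descent with one drawn
    from j (with a_ii = 1 + F_i handled by the same formula plus 1).
    """
    order = ped.topological_order()
    parents = ped.parents()
    index = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    rng = np.random.default_rng(seed)
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    next_founder = 1
    for ind in order:
        i = index[ind]
        for slot, par in enumerate(parents[ind]):
            if par in index:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[i, slot] = alleles[index[par], 0]
                sel = pick == 1
                alleles[i, slot][sel] = alleles[index[par], 1][sel]
            else:
                alleles[i, slot] = next_founder + slot * n
        next_founder += 1
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = sum(
                (alleles[i, a] == alleles[j, b]).mean()
                for a in range(2) for b in range(2)) / 4.0
            if i == j:
                # kinship with self = (1 + F)/2; a_ii = 2*kinship
                A[i, i] = 2.0 * ibd
            else:
                A[i, j] = A[j, i] = 2.0 * ibd
    return A, order
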