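"""Shared fixtures: deterministic hand-built and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from introtrace.data import MISSING, GenotypeDataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def hw_genotypes(
    n: int, freqs_per_locus: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Random-union-of-gametes diploid genotypes; alleles coded 101, 102, ..."""
    L = len(freqs_per_locus)
    calls = np.empty((n, L, 2), dtype=np.int64)
    for j, freqs in enumerate(freqs_per_locus):
        A = len(freqs)
        calls[:, j, 0] = rng.choice(A, size=n, p=freqs) + 101
        calls[:, j, 1] = rng.choice(A, size=n, p=freqs) + 101
    return calls


def hw_dataset(
    pop_sizes: dict[str, int],
    freqs_per_pop: dict[str, list[np.ndarray]],
    seed: int = 0,
) -> GenotypeDataset:
    """Multi-population random-mating dataset with given allele frequencies."""
    rng = np.random.default_rng(seed)
    individuals, pops, blocks = [], [], []
    for label, n in pop_sizes.items():
        blocks.append(hw_genotypes(n, freqs_per_pop[label], rng))
        individuals += [f"{label}_{i}" for i in range(n)]
        pops += [label] * n
    L = blocks[0].shape[1]
    return GenotypeDataset(
        individuals, pops, [f"L{j+1}" for j in range(L)], np.concatenate(blocks)
    )


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """2 populations x 3 individuals x 2 loci, one missing call."""
    calls = np.array(
        [
            [[150, 154], [200, 200]],
            [[150, 150], [200, 204]],
            [[154, 154], [MISSING, MISSING]],
            [[158, 158], [204, 204]],
            [[150, 158], [204, 208]],
            [[158, 158], [208, 208]],
        ]
    )
    return GenotypeDataset(
        [f"i{k}" for k in range(6)],
        ["P1"] * 3 + ["P2"] * 3,
        ["locA", "locB"],
        calls,
    )


@pytest.fixture
def fixed_difference_dataset() -> GenotypeDataset:
    """Two populations fixed for different alleles at every locus."""
    n = 12
    calls_a = np.full((n, 4, 2), 100)
    calls_b = np.full((n, 4, 2), 120)
    return GenotypeDataset(
        [f"a{k}" for k in range(n)] + [f"b{k}" for k in range(n)],
        ["A"] * n + ["B"] * n,
        [f"L{j}" for j in range(4)],
        np.concatenate([calls_a, calls_b]),
    )
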