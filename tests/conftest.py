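"""Shared fixtures: tiny hand-built panels/matrices and one session bundle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ambropop.datatypes import GenotypeMatrix, SamplePanel
from ambropop.simulate import SimulationConfig, simulate_bundle


def make_panel(pop_sizes: dict[str, int], habitats: dict[str, str] | None = None,
               regions: dict[str, str] | None = None,
               coords: dict[str, tuple[float, float]] | None = None,
               replicate_groups: dict[str, list[str]] | None = None
               ) -> SamplePanel:
    """Build a panel from population -> size, with optional overrides."""
    rows = []
    rep_of = {}
    for g, members in (replicate_groups or {}).items():
        for m in members:
            rep_of[m] = g
    for i, (pop, n) in enumerate(pop_sizes.items()):
        hab = (habitats or {}).get(pop, "weedy" if i % 2 == 0 else "wild")
        reg = (regions or {}).get(pop, "R1")
        lat, lon = (coords or {}).get(pop, (40.0 + i, -83.0))
        for k in range(n):
            sid = f"{pop}-{k + 1}"
            rows.append((sid, pop, hab, reg, lat, lon, rep_of.get(sid, pd.NA)))
    return SamplePanel(pd.DataFrame(
        rows, columns=["sample_id", "population_id", "habitat", "region",
                       "latitude", "longitude", "replicate_group"]))


def make_genotypes(dosages: np.ndarray, samples: list[str],
                   chrom: str = "c1") -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=np.int8)
    loci = pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, dosages.shape[0] + 1),
        "ref": "A", "alt": "T"})
    return GenotypeMatrix(loci, samples, dosages)


def random_micro_instance(rng: np.random.Generator
                          ) -> tuple[GenotypeMatrix, SamplePanel]:
    """Random 3-population instance (<= 6 samples/pop, <= 8 loci, missingness)."""
    sizes = {f"P{i}": int(rng.integers(2, 7)) for i in range(3)}
    panel = make_panel(sizes)
    n = sum(sizes.values())
    n_loci = int(rng.integers(2, 9))
    d = rng.integers(0, 3, size=(n_loci, n)).astype(np.int8)
    miss = rng.random((n_loci, n)) < 0.1
    d[miss] = -1
    # keep at least 2 genotyped per population per locus for determinate stats
    start = 0
    for pop, size in sizes.items():
        block = d[:, start:start + size]
        for li in range(n_loci):
            while (block[li] != -1).sum() < 2:
                block[li, int(rng.integers(size))] = int(rng.integers(0, 3))
        start += size
    return make_genotypes(d, panel.sample_ids), panel


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic bundle shared across tests."""
    return simulate_bundle(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down generator config for fast end-to-end tests."""
    return SimulationConfig(seed=5, n_loci=400, n_transcripts=600,
                            n_ged_genes=60, n_de_genes_per_pair=15,
                            n_reference_transcripts=40,
                            n_unique_transcripts_per_pop=8,
                            n_shared_weedy_unique=3)
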