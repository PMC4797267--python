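"""Shared fixtures: small hand-built genomes and a multi-seed bank of
synthetic experiments reused by the recovery tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import oxichip as ox

RECOVERY_SEEDS = tuple(range(1, 21))


@pytest.fixture
def toy_genome() -> ox.GenomeModel:
    """10 kb single-chromosome genome with a fixed sequence."""
    rng = np.random.default_rng(123)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
    return ox.GenomeModel(chroms=[("chrT", 10_000)], sequences={"chrT": seq})


@pytest.fixture
def plus_gene() -> ox.GeneModel:
    """Coding + strand gene: tx 2000-5000, two exons, CDS inside."""
    return ox.GeneModel(
        name="plus1",
        chrom="chrT",
        strand="+",
        tx_start=2000,
        tx_end=5000,
        cds_start=2100,
        cds_end=4900,
        exons=[(2000, 3000), (4000, 5000)],
    )


@pytest.fixture
def minus_gene() -> ox.GeneModel:
    """Coding - strand gene: tx 6000-8000, two exons."""
    return ox.GeneModel(
        name="minus1",
        chrom="chrT",
        strand="-",
        tx_start=6000,
        tx_end=8000,
        cds_start=6200,
        cds_end=7800,
        exons=[(6000, 6800), (7200, 8000)],
    )


@dataclass
class SeedRun:
    """One synthetic experiment and everything derived from it."""

    seed: int
    config: ox.SimConfig
    genome: ox.GenomeModel
    genes: list
    truth: pd.DataFrame
    results: "ox.DifferentialOccupancyResults"
    matched: pd.DataFrame  # truth joined to classified sites by center
    called_union: list  # peaks from the plumbing caller, both conditions


def _match_truth(truth: pd.DataFrame, sites: pd.DataFrame, window: int) -> pd.DataFrame:
    """Join each truth site to the classified site nearest its center."""
    rows = []
    for t in truth.itertuples(index=False):
        sub = sites[(sites["chrom"] == t.chrom) & (abs(sites["center"] - t.center) <= window // 2)]
        if len(sub):
            nearest = sub.iloc[(sub["center"] - t.center).abs().argmin()]
            rows.append({**t._asdict(), "label": nearest["label"],
                         "count_A": nearest["count_A"], "count_B": nearest["count_B"]})
        else:
            rows.append({**t._asdict(), "label": None, "count_A": None, "count_B": None})
    return pd.DataFrame(rows)


def _run_seed(seed: int) -> SeedRun:
    cfg = ox.SimConfig(seed=seed)
    genome, genes = ox.generate_genome(cfg)
    reads_a, reads_b, truth_sites, peaks_a, peaks_b = ox.simulate_two_condition_chip(
        genome, genes, cfg
    )
    results = ox.compare_conditions(peaks_a, peaks_b, reads_a, reads_b)
    truth = ox.truth_table(truth_sites)
    matched = _match_truth(truth, results.sites, window=200)

    # site-free simulations provide matched-depth uniform controls for the caller
    ctrl_cfg = ox.SimConfig(seed=seed + 10_000, n_induced=0, n_repressed=0, n_common=0)
    ctrl_a, ctrl_b, *_ = ox.simulate_two_condition_chip(genome, genes, ctrl_cfg)
    called = ox.call_peaks(reads_a, ctrl_a, genome) + ox.call_peaks(reads_b, ctrl_b, genome)

    return SeedRun(
        seed=seed,
        config=cfg,
        genome=genome,
        genes=genes,
        truth=truth,
        results=results,
        matched=matched,
        called_union=called,
    )


@pytest.fixture(scope="session")
def seed_runs() -> list[SeedRun]:
    """Twenty independent synthetic experiments at the default conditions."""
    return [_run_seed(seed) for seed in RECOVERY_SEEDS]


@pytest.fixture(scope="session")
def single_run(seed_runs) -> SeedRun:
    return seed_runs[0]
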