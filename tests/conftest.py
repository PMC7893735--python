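"""Shared fixtures: a desk-scale study genome, tissue references, called
DMRs and a reference panel, plus factories for hand-built toy maps."""

from __future__ import annotations

import numpy as np
import pytest

from cfmeth import (
    COHORT_GENOME,
    CpGMap,
    TissueMethylome,
    build_genome,
    build_reference_panel,
    call_dmrs,
    group_mean_betas,
    segment_candidate_regions,
    simulate_tissue_methylomes,
)
from cfmeth.genome import INTERGENIC


def make_toy_map(
    sites_by_chrom: dict[str, list[int]],
    chrom_length: int = 10_000,
    window_bp: int = 500,
) -> CpGMap:
    """Hand-built CpG map: explicit site positions, uniform context."""
    names = tuple(sites_by_chrom)
    parts = [np.asarray(sorted(v), dtype=np.int64) for v in sites_by_chrom.values()]
    site_pos = np.concatenate(parts) if parts else np.array([], np.int64)
    site_offsets = np.concatenate([[0], np.cumsum([p.size for p in parts])]).astype(np.int64)
    n_win = max(1, chrom_length // window_bp)
    window_offsets = np.arange(len(names) + 1, dtype=np.int64) * n_win
    counts = np.zeros(n_win * len(names), dtype=np.int64)
    for c, p in enumerate(parts):
        wi = c * n_win + np.clip(p // window_bp, 0, n_win - 1)
        np.add.at(counts, wi, 1)
    m = CpGMap(
        chrom_names=names,
        chrom_lengths=np.full(len(names), chrom_length, dtype=np.int64),
        site_pos=site_pos,
        site_offsets=site_offsets,
        site_region=np.full(site_pos.shape, INTERGENIC, dtype=np.uint8),
        window_bp=window_bp,
        window_offsets=window_offsets,
        window_gc=np.full(counts.shape, 0.4),
        window_cpg_density=counts * (1000.0 / window_bp),
        window_region=np.full(counts.shape, INTERGENIC, dtype=np.uint8),
        window_is_island=np.zeros(counts.shape, dtype=bool),
    )
    m.validate()
    return m


def make_methylomes(
    n_sites: int, mal_beta: float | np.ndarray, ben_beta: float | np.ndarray,
    n_mal: int = 2, n_ben: int = 2,
) -> list[TissueMethylome]:
    """Noise-free methylomes with constant (or given) per-site beta vectors."""
    mal = np.broadcast_to(np.asarray(mal_beta, float), (n_sites,)).copy()
    ben = np.broadcast_to(np.asarray(ben_beta, float), (n_sites,)).copy()
    out = [TissueMethylome(f"mal_{i}", "malignant", mal.copy()) for i in range(n_mal)]
    out += [TissueMethylome(f"ben_{i}", "benign", ben.copy()) for i in range(n_ben)]
    return out


@pytest.fixture(scope="session")
def cohort_map():
    return build_genome(COHORT_GENOME, seed=7)


@pytest.fixture(scope="session")
def tissue_sim(cohort_map):
    return simulate_tissue_methylomes(cohort_map, seed=7)


@pytest.fixture(scope="session")
def called_dmrs(cohort_map, tissue_sim):
    tissues, _ = tissue_sim
    regions = segment_candidate_regions(cohort_map)
    return call_dmrs(regions, tissues, cohort_map)


@pytest.fixture(scope="session")
def hypo_panel(cohort_map, tissue_sim, called_dmrs):
    tissues, _ = tissue_sim
    hypo = [d for d in called_dmrs if d.direction == "hypo"]
    return build_reference_panel(hypo, tissues, cohort_map)


@pytest.fixture(scope="session")
def tissue_refs(tissue_sim):
    tissues, _ = tissue_sim
    return group_mean_betas(tissues)
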