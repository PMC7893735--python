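"""Differentially methylated region (DMR) calling between tissue groups.

Candidate regions are maximal runs of CpG sites separated by at most
``max_gap_bp``; per region, per-sample mean methylation is compared between
the malignant and benign groups with a two-sample location test (rank-based
by default, Welch t optional), Benjamini-Hochberg corrected across regions.
A region is a DMR when q <= alpha and |delta| >= min_delta; direction is
hyper (higher in malignancy) for delta > 0, hypo for delta < 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientReplicatesError
from .genome import CpGMap

MALIGNANT, BENIGN = "malignant", "benign"


@dataclass(frozen=True)
class Region:
    """A candidate interval, 0-based half-open."""

    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class DMR:
    """A called differentially methylated region."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_beta_mal: float
    mean_beta_ben: float
    delta: float  # mean_beta_mal - mean_beta_ben
    direction: str  # "hyper" iff delta > 0 else "hypo"
    p_value: float
    q_value: float

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def segment_candidate_regions(
    cpg_map: CpGMap, min_cpgs: int = 4, max_gap_bp: int = 500
) -> list[Region]:
    """Maximal CpG runs with inter-CpG gap <= max_gap_bp and >= min_cpgs sites.

    Returned regions are sorted and non-overlapping; a region spans from its
    first site to 2 bp past its last site (the CpG dinucleotide footprint).
    """
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be at least 1")
    regions: list[Region] = []
    for c, name in enumerate(cpg_map.chrom_names):
        pos = cpg_map.chrom_sites(c)
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [pos.size]])
        for s, e in zip(starts, ends):
            if e - s >= min_cpgs:
                regions.append(Region(name, int(pos[s]), int(pos[e - 1]) + 2))
    return regions


def cpg_density(interval, cpg_map: CpGMap) -> float:
    """CpG sites per kb in a half-open interval (accepts Region/DMR/tuple)."""
    if hasattr(interval, "chrom"):
        chrom, start, end = interval.chrom, interval.start, interval.end
    else:
        chrom, start, end = interval
    if end <= start:
        raise ValueError(f"zero-length interval [{start}, {end})")
    lo, hi = cpg_map.sites_in(chrom, start, end)
    return (hi - lo) * 1000.0 / (end - start)


def _region_sample_means(regions, methylomes, cpg_map):
    """(n_regions x n_samples) matrix of per-sample mean beta per region."""
    betas = np.stack([m.beta for m in methylomes])
    out = np.empty((len(regions), len(methylomes)))
    n_cpgs = np.empty(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        lo, hi = cpg_map.sites_in(r.chrom, r.start, r.end)
        n_cpgs[i] = hi - lo
        out[i] = betas[:, lo:hi].mean(axis=1) if hi > lo else np.nan
    return out, n_cpgs


def _two_sample_p(x: np.ndarray, y: np.ndarray, test: str) -> float:
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    if test == "ranksum":
        return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    if test == "ttest":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    raise ValueError(f"unknown test {test!r}")


def call_dmrs(
    regions: Sequence[Region],
    methylomes,
    cpg_map: CpGMap,
    min_delta: float = 0.2,
    alpha: float = 0.05,
    test: str = "ranksum",
) -> list[DMR]:
    """Call DMRs over candidate regions from grouped tissue methylomes.

    Requires >= 2 samples per group.  Multiple-testing correction (BH) runs
    across candidate regions; equal p-values are ordered by larger |delta|
    first so output is deterministic.  Output is sorted by coordinate and
    inherits the candidates' non-overlap.
    """
    mal = [m for m in methylomes if m.group == MALIGNANT]
    ben = [m for m in methylomes if m.group == BENIGN]
    if len(mal) < 2 or len(ben) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 samples per group, got {len(mal)} malignant / {len(ben)} benign"
        )
    regions = [r for r in regions]
    if not regions:
        return []
    ordered = mal + ben
    means, n_cpgs = _region_sample_means(regions, ordered, cpg_map)
    keep = n_cpgs > 0
    mal_means = means[:, : len(mal)]
    ben_means = means[:, len(mal) :]
    delta = mal_means.mean(axis=1) - ben_means.mean(axis=1)
    pvals = np.ones(len(regions))
    for i in np.flatnonzero(keep):
        pvals[i] = _two_sample_p(mal_means[i], ben_means[i], test)

    order = np.lexsort((-np.abs(delta), pvals))  # p asc, ties by |delta| desc
    qvals = np.empty_like(pvals)
    qvals[order] = multipletests(pvals[order], method="fdr_bh")[1]

    out: list[DMR] = []
    for i in np.flatnonzero(keep):
        if qvals[i] <= alpha and abs(delta[i]) >= min_delta:
            r = regions[i]
            out.append(
                DMR(
                    chrom=r.chrom, start=r.start, end=r.end, n_cpgs=int(n_cpgs[i]),
                    mean_beta_mal=float(mal_means[i].mean()),
                    mean_beta_ben=float(ben_means[i].mean()),
                    delta=float(delta[i]),
                    direction="hyper" if delta[i] > 0 else "hypo",
                    p_value=float(pvals[i]), q_value=float(qvals[i]),
                )
            )
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def hypo_dmrs(dmrs: Sequence[DMR]) -> list[DMR]:
    """The hypomethylated subset — the default marker candidates."""
    return [d for d in dmrs if d.direction == "hypo"]


def hyper_dmrs(dmrs: Sequence[DMR]) -> list[DMR]:
    return [d for d in dmrs if d.direction == "hyper"]
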