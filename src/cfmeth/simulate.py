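"""Synthetic study generator: tissues, plasma fragment sets, and cohorts.

Everything downstream of sequencing is emulated with known ground truth:

* tissue methylomes for two groups (malignant / benign) with planted
  hyper- and hypo-DMRs — hyper-DMRs preferentially in CpG-dense (island)
  territory, hypo-DMRs in sparse territory, reproducing the density
  asymmetry seen in real tumor methylomes;
* plasma samples as mixtures of tumor- and non-tumor-derived fragments,
  with tumor fraction as the hidden parameter, origin-specific fragment
  length distributions (non-tumor mononucleosomal mode at 167 bp, tumor
  fragments stochastically shorter), per-CpG binary calls drawn from the
  origin group's tissue methylation means, and coverage depletion in
  CpG-dense / promoter windows;
* cohort tables with malignancy labels, BI-RADS 4 subcategories, ordinal
  imaging scores, and stage/grade covariates; malignant tumor fractions
  increase with stage.

All operations are bit-reproducible for a given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, InsufficientReplicatesError
from .genome import PROMOTER, CpGMap, GenomeConfig, build_genome
from .fragments import FragmentSet
from . import dmr as _dmr_mod

MALIGNANT, BENIGN = "malignant", "benign"
TUMOR, NONTUMOR = "tumor", "nontumor"
STAGES = ("0", "I", "II", "III")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedDMR:
    chrom: str
    start: int
    end: int
    direction: str  # "hyper" | "hypo" (relative to malignant)
    delta: float  # signed planted group-mean methylation difference


@dataclass
class SimTruth:
    """Ground truth attached to simulated objects for recovery tests."""

    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    tumor_fraction: float | None = None
    fragment_origins: np.ndarray | None = None  # bool, True = tumor


@dataclass
class TissueMethylome:
    sample_id: str
    group: str  # "malignant" | "benign"
    beta: np.ndarray  # per-CpG methylation level, aligned to CpGMap.site_pos


@dataclass
class PlasmaSample:
    sample_id: str
    label: str  # "malignant" | "benign"
    fragments: FragmentSet
    truth: SimTruth | None = None


@dataclass
class CohortRecord:
    sample_id: str
    label: str
    cohort: str  # "discovery" | "validation"
    birads_sub: str  # "4a" | "4b" | "4c"
    mammography_score: int  # ordinal 1-5
    ultrasound_score: int  # ordinal 1-5
    stage: str | None = None  # "0","I","II","III" for malignant, else None
    grade: int | None = None  # ordinal 1-3 for malignant


# ---------------------------------------------------------------------------
# tissue methylomes with planted DMRs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DmrPlantSpec:
    """How DMRs are planted into the tissue methylomes.

    Hyper-DMRs are placed on the densest candidate CpG runs (islands),
    hypo-DMRs on runs drawn from the sparse half; deltas are magnitudes and
    applied as +delta (hyper) / -delta (hypo) to the malignant group mean.
    Per-CpG beta values are Beta(mean * c, (1 - mean) * c) draws with
    concentration ``c = noise_concentration``.
    """

    n_hyper: int = 4
    n_hypo: int = 16
    delta_hyper: float = 0.40
    delta_hypo: float = 0.50
    width_bp: int | None = None  # None = whole candidate run
    noise_concentration: float = 30.0
    sample_effect_sd: float = 0.01  # per-sample global shift of the mean
    island_beta: float = 0.15
    promoter_beta: float = 0.55
    body_beta: float = 0.85
    min_region_cpgs: int = 8
    regions: tuple[PlantedDMR, ...] | None = None  # explicit placement override

    def validate(self) -> None:
        if self.n_hyper < 0 or self.n_hypo < 0:
            raise ConfigError("planted DMR counts must be non-negative")
        for d in (self.delta_hyper, self.delta_hypo):
            if not 0.0 <= d <= 1.0:
                raise ConfigError("planted delta magnitudes must be in [0, 1]")
        if self.noise_concentration <= 0:
            raise ConfigError("noise_concentration must be positive")
        if self.regions is not None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for r in self.regions:
                by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
            for ivs in by_chrom.values():
                ivs.sort()
                for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                    if s2 < e1:
                        raise ConfigError("planted DMRs overlap")


def _base_mean_beta(cpg_map: CpGMap, spec: DmrPlantSpec) -> np.ndarray:
    """Shared (both-group) mean methylation per site from genomic context."""
    mean = np.full(cpg_map.n_sites, spec.body_beta)
    mean[cpg_map.site_region == PROMOTER] = spec.promoter_beta
    if cpg_map.window_is_island is not None:
        chrom = cpg_map.site_chrom
        for c in range(cpg_map.n_chromosomes):
            sel = chrom == c
            wi = cpg_map.window_offsets[c] + cpg_map.site_pos[sel] // cpg_map.window_bp
            wi = np.clip(wi, cpg_map.window_offsets[c], cpg_map.window_offsets[c + 1] - 1)
            island = cpg_map.window_is_island[wi]
            vals = mean[sel]
            vals[island] = spec.island_beta
            mean[sel] = vals
    return mean


def _plant_dmrs(cpg_map: CpGMap, spec: DmrPlantSpec, rng: np.random.Generator) -> list[PlantedDMR]:
    if spec.regions is not None:
        return list(spec.regions)
    runs = _dmr_mod.segment_candidate_regions(cpg_map, min_cpgs=spec.min_region_cpgs,
                                              max_gap_bp=500)
    if spec.width_bp is not None:
        clipped = []
        for r in runs:
            if r.end - r.start > spec.width_bp:
                mid = (r.start + r.end) // 2
                r = replace(r, start=mid - spec.width_bp // 2, end=mid + spec.width_bp // 2)
            clipped.append(r)
        runs = clipped
    if len(runs) < spec.n_hyper + spec.n_hypo:
        raise ConfigError(
            f"genome yields {len(runs)} candidate CpG runs; cannot plant "
            f"{spec.n_hyper + spec.n_hypo} DMRs"
        )
    dens = np.array([_dmr_mod.cpg_density((r.chrom, r.start, r.end), cpg_map) for r in runs])
    order = np.argsort(-dens, kind="stable")
    hyper_idx = list(order[: spec.n_hyper])

    def touches_island(r) -> bool:
        if cpg_map.window_is_island is None:
            return False
        c = cpg_map.chrom_index(r.chrom)
        lo = cpg_map.window_offsets[c] + r.start // cpg_map.window_bp
        hi = cpg_map.window_offsets[c] + (r.end - 1) // cpg_map.window_bp + 1
        return bool(cpg_map.window_is_island[lo:hi].any())

    sparse_pool = [
        i for i in order[len(order) // 2 :]
        if i not in hyper_idx and not touches_island(runs[i])
    ]
    if len(sparse_pool) < spec.n_hypo:
        sparse_pool = [
            i for i in order[spec.n_hyper :] if not touches_island(runs[i])
        ] or [i for i in order[spec.n_hyper :]]
    hypo_idx = list(rng.choice(sparse_pool, size=spec.n_hypo, replace=False)) if spec.n_hypo else []

    def island_core(r):
        """Clip a hyper target to its island windows: flanks are already
        methylated and cannot gain, so the gain lives in the island core."""
        if cpg_map.window_is_island is None:
            return r.start, r.end
        c = cpg_map.chrom_index(r.chrom)
        lo = cpg_map.window_offsets[c] + r.start // cpg_map.window_bp
        hi = cpg_map.window_offsets[c] + (r.end - 1) // cpg_map.window_bp + 1
        isl = np.flatnonzero(cpg_map.window_is_island[lo:hi])
        if isl.size == 0:
            return r.start, r.end
        w0 = (r.start // cpg_map.window_bp + isl[0]) * cpg_map.window_bp
        w1 = (r.start // cpg_map.window_bp + isl[-1] + 1) * cpg_map.window_bp
        return max(r.start, w0), min(r.end, w1)

    planted = [
        PlantedDMR(runs[i].chrom, *island_core(runs[i]), "hyper", +spec.delta_hyper)
        for i in hyper_idx
    ] + [
        PlantedDMR(runs[i].chrom, runs[i].start, runs[i].end, "hypo", -spec.delta_hypo)
        for i in hypo_idx
    ]
    planted.sort(key=lambda d: (d.chrom, d.start))
    return planted


def simulate_tissue_methylomes(
    cpg_map: CpGMap,
    n_mal: int = 9,
    n_ben: int = 10,
    dmr_spec: DmrPlantSpec | None = None,
    seed: int = 0,
) -> tuple[list[TissueMethylome], SimTruth]:
    """Tissue reference methylomes for both groups with planted DMRs.

    Outside planted DMRs the two group means are identical; inside they
    differ by the planted signed delta.  Means pushed outside [0, 1] are
    clamped with a warning.
    """
    dmr_spec = dmr_spec or DmrPlantSpec()
    dmr_spec.validate()
    if n_mal < 0 or n_ben < 0:
        raise ConfigError("sample counts must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    planted = _plant_dmrs(cpg_map, dmr_spec, rng)

    mean_ben = _base_mean_beta(cpg_map, dmr_spec)
    mean_mal = mean_ben.copy()
    for d in planted:
        lo, hi = cpg_map.sites_in(d.chrom, d.start, d.end)
        mean_mal[lo:hi] += d.delta
    for arr, name in ((mean_mal, "malignant"), (mean_ben, "benign")):
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} {name} group-mean values clamped into [0, 1]",
                stacklevel=2,
            )
            np.clip(arr, 0.0, 1.0, out=arr)

    c = dmr_spec.noise_concentration
    tissues: list[TissueMethylome] = []
    for group, n, mean in ((MALIGNANT, n_mal, mean_mal), (BENIGN, n_ben, mean_ben)):
        for i in range(n):
            shift = rng.normal(0.0, dmr_spec.sample_effect_sd)
            m = np.clip(mean + shift, 1e-3, 1.0 - 1e-3)
            beta = rng.beta(m * c, (1.0 - m) * c)
            tissues.append(
                TissueMethylome(sample_id=f"{group[:3]}_{i + 1:02d}", group=group, beta=beta)
            )
    return tissues, SimTruth(planted_dmrs=planted)


def group_mean_betas(tissues: Sequence[TissueMethylome]) -> tuple[np.ndarray, np.ndarray]:
    """(malignant mean, benign mean) per-site vectors over tissue samples."""
    mal = [t.beta for t in tissues if t.group == MALIGNANT]
    ben = [t.beta for t in tissues if t.group == BENIGN]
    if not mal or not ben:
        raise InsufficientReplicatesError("both tissue groups are required")
    return np.mean(mal, axis=0), np.mean(ben, axis=0)


# ---------------------------------------------------------------------------
# fragment length models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentLengthModel:
    """Discretized cfDNA fragment length distribution.

    A left-skewed mononucleosomal peak plus a sharp spike at the mode (the
    well-protected nucleosome + linker length) and a small di-nucleosomal
    satellite.  The non-tumor default has its mode at 167 bp; the tumor
    default is the same family shifted to 145 bp, i.e. stochastically
    shorter.
    """

    mode_bp: int = 167
    scale_bp: float = 20.0
    skew: float = -4.0
    sharp_weight: float = 0.10
    sharp_halfwidth: int = 3
    dinucleosome_weight: float = 0.06
    dinucleosome_mode: int = 334
    dinucleosome_scale: float = 25.0
    min_bp: int = 30
    max_bp: int = 499


NONTUMOR_LENGTHS = FragmentLengthModel()
TUMOR_LENGTHS = FragmentLengthModel(
    mode_bp=145, scale_bp=18.0, skew=-3.0, sharp_weight=0.06,
    dinucleosome_weight=0.04, dinucleosome_mode=310,
)

_PMF_CACHE: dict[FragmentLengthModel, tuple[np.ndarray, np.ndarray]] = {}


def _length_pmf(model: FragmentLengthModel) -> tuple[np.ndarray, np.ndarray]:
    """(grid, pmf) of the discretized length distribution; cached per model."""
    cached = _PMF_CACHE.get(model)
    if cached is not None:
        return cached
    grid = np.arange(model.min_bp, model.max_bp + 1)
    # locate the skew-normal mode numerically, then anchor it at mode_bp
    probe = np.linspace(-4 * model.scale_bp, 4 * model.scale_bp, 4001)
    offset = probe[np.argmax(sps.skewnorm.pdf(probe, model.skew, loc=0.0, scale=model.scale_bp))]
    main = sps.skewnorm.pdf(grid, model.skew, loc=model.mode_bp - offset, scale=model.scale_bp)
    main /= main.sum()
    h = model.sharp_halfwidth
    sharp = np.maximum(0.0, h + 1 - np.abs(grid - model.mode_bp)).astype(float)
    sharp /= sharp.sum()
    dinuc = sps.norm.pdf(grid, model.dinucleosome_mode, model.dinucleosome_scale)
    dinuc /= dinuc.sum()
    w_sharp, w_di = model.sharp_weight, model.dinucleosome_weight
    pmf = (1.0 - w_sharp - w_di) * main + w_sharp * sharp + w_di * dinuc
    pmf /= pmf.sum()
    _PMF_CACHE[model] = (grid, pmf)
    return grid, pmf


def sample_fragment_length(
    origin: str,
    rng: np.random.Generator,
    model: FragmentLengthModel | None = None,
    size: int | None = None,
):
    """Draw fragment length(s) in bp for a given origin ("tumor"/"nontumor")."""
    if model is None:
        if origin == TUMOR:
            model = TUMOR_LENGTHS
        elif origin == NONTUMOR:
            model = NONTUMOR_LENGTHS
        else:
            raise ValueError(f"unknown origin {origin!r}")
    grid, pmf = _length_pmf(model)
    draw = rng.choice(grid, size=size, p=pmf)
    return int(draw) if size is None else draw.astype(np.int64)


# ---------------------------------------------------------------------------
# plasma samples
# ---------------------------------------------------------------------------

def _window_weights(
    cpg_map: CpGMap, depletion_weight: float, promoter_multiplier: float
) -> np.ndarray:
    """Fragment-start sampling probability per window.

    exp(-w * density_z) with w doubled (``promoter_multiplier``) in promoter
    windows: fragments are depleted where CpG density is high, more so at
    promoters, emulating preferential nucleolytic loss of open chromatin.
    """
    dens = cpg_map.window_cpg_density
    sd = dens.std()
    z = (dens - dens.mean()) / sd if sd > 0 else np.zeros_like(dens)
    w = depletion_weight * np.where(cpg_map.window_region == PROMOTER, promoter_multiplier, 1.0)
    weights = np.exp(-w * z)
    return weights / weights.sum()


def simulate_plasma_sample(
    cpg_map: CpGMap,
    refs,
    tumor_fraction: float,
    n_fragments: int,
    noise: float = 0.01,
    seed: int = 0,
    depletion_weight: float = 0.5,
    promoter_multiplier: float = 2.0,
    tumor_lengths: FragmentLengthModel = TUMOR_LENGTHS,
    nontumor_lengths: FragmentLengthModel = NONTUMOR_LENGTHS,
    sample_id: str = "plasma",
    label: str | None = None,
) -> PlasmaSample:
    """Simulate one plasma cfDNA specimen as a tumor/non-tumor mixture.

    ``refs`` is either a list of :class:`TissueMethylome` or a precomputed
    ``(malignant_mean, benign_mean)`` pair.  Each fragment's origin is
    Bernoulli(tumor_fraction); its covered CpG calls are Bernoulli draws from
    the origin group's mean beta, each flipped with probability ``noise``
    (bisulfite conversion error).  Fragment starts are drawn with
    CpG-density/promoter depletion weighting.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError(f"tumor_fraction must be in [0, 1], got {tumor_fraction}")
    if isinstance(refs, tuple):
        mal_mean, ben_mean = refs
    else:
        mal_mean, ben_mean = group_mean_betas(refs)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))

    origins = rng.random(n_fragments) < tumor_fraction
    lengths = np.empty(n_fragments, dtype=np.int64)
    n_t = int(origins.sum())
    if n_t:
        lengths[origins] = sample_fragment_length(TUMOR, rng, tumor_lengths, size=n_t)
    if n_fragments - n_t:
        lengths[~origins] = sample_fragment_length(
            NONTUMOR, rng, nontumor_lengths, size=n_fragments - n_t
        )

    weights = _window_weights(cpg_map, depletion_weight, promoter_multiplier)
    wi = rng.choice(cpg_map.n_windows, size=n_fragments, p=weights)
    chrom = np.searchsorted(cpg_map.window_offsets, wi, side="right") - 1
    local = wi - cpg_map.window_offsets[chrom]
    start = local * cpg_map.window_bp + rng.integers(0, cpg_map.window_bp, n_fragments)
    start = np.minimum(start, cpg_map.chrom_lengths[chrom] - lengths)
    start = np.maximum(start, 0)
    end = start + lengths

    # covered CpG sites per fragment (global site index ranges)
    lo = np.empty(n_fragments, dtype=np.int64)
    hi = np.empty(n_fragments, dtype=np.int64)
    for c in range(cpg_map.n_chromosomes):
        sel = chrom == c
        if not sel.any():
            continue
        base = cpg_map.site_offsets[c]
        pos_c = cpg_map.site_pos[base : cpg_map.site_offsets[c + 1]]
        lo[sel] = base + np.searchsorted(pos_c, start[sel], side="left")
        hi[sel] = base + np.searchsorted(pos_c, end[sel], side="left")
    counts = hi - lo
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1])
    flat_site = (
        np.repeat(lo, counts) + np.arange(total) - np.repeat(offsets[:-1], counts)
    ) if total else np.array([], dtype=np.int64)

    origin_per_call = np.repeat(origins, counts)
    p = np.where(origin_per_call, mal_mean[flat_site], ben_mean[flat_site])
    p_eff = p * (1.0 - noise) + (1.0 - p) * noise
    states = (rng.random(total) < p_eff).astype(np.uint8)

    fragments = FragmentSet(
        chrom=chrom, start=start, end=end, cpg_offsets=offsets,
        cpg_pos=cpg_map.site_pos[flat_site], cpg_state=states,
        chrom_names=cpg_map.chrom_names,
    )
    truth = SimTruth(tumor_fraction=float(tumor_fraction), fragment_origins=origins)
    return PlasmaSample(sample_id=sample_id, label=label, fragments=fragments, truth=truth)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """One cohort's composition and signal strengths.

    Defaults mirror the discovery design: 77 malignant vs 77 benign BI-RADS 4
    lesions, 20k methylation-called fragments per plasma sample, malignant
    tumor fractions drawn from stage-conditional Gamma distributions whose
    means increase with stage, and ordinal 1-5 imaging scores whose
    standalone discrimination is deliberately imperfect.
    """

    n_malignant: int = 77
    n_benign: int = 77
    cohort_name: str = "discovery"
    n_fragments: int = 20_000
    conversion_noise: float = 0.01
    stage_mix: tuple[tuple[str, float], ...] = (
        ("0", 0.06), ("I", 0.40), ("II", 0.34), ("III", 0.20),
    )
    stage_tumor_fraction: tuple[tuple[str, float], ...] = (
        ("0", 0.005), ("I", 0.01), ("II", 0.02), ("III", 0.04),
    )
    tumor_fraction_shape: float = 3.0
    imaging_signal: float = 1.2
    ultrasound_signal: float = 1.1
    depletion_weight: float = 0.5
    promoter_multiplier: float = 2.0

    def validate(self) -> None:
        if self.n_malignant < 2 or self.n_benign < 2:
            raise ConfigError("cohort sizes must be at least 2 per class")
        if abs(sum(p for _, p in self.stage_mix) - 1.0) > 1e-9:
            raise ConfigError("stage_mix probabilities must sum to 1")
        if self.n_fragments <= 0:
            raise ConfigError("n_fragments must be positive")
        if not 0.0 <= self.conversion_noise < 0.5:
            raise ConfigError("conversion_noise must be in [0, 0.5)")


def _ordinal_score(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(latent), 1, 5).astype(int)


def simulate_cohort(
    cpg_map: CpGMap,
    tissues: Sequence[TissueMethylome],
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[list[PlasmaSample], list[CohortRecord]]:
    """Simulate one cohort: plasma samples plus the clinical covariate table.

    Malignant samples draw their hidden tumor fraction from the
    stage-conditional Gamma distributions; benign samples carry tumor
    fraction 0.  Imaging scores are label-shifted ordinal draws.
    """
    config = config or CohortConfig()
    config.validate()
    ss = np.random.SeedSequence([int(seed), 37])
    rng = np.random.default_rng(ss)
    refs = group_mean_betas(tissues)

    stages, probs = zip(*config.stage_mix)
    tf_by_stage = dict(config.stage_tumor_fraction)
    shape = config.tumor_fraction_shape

    plan: list[tuple[str, str | None, float]] = []  # (label, stage, tumor_fraction)
    for _ in range(config.n_malignant):
        stage = str(rng.choice(stages, p=probs))
        mean_tf = tf_by_stage[stage]
        tf = float(np.clip(rng.gamma(shape, mean_tf / shape), 0.0, 0.5))
        plan.append((MALIGNANT, stage, tf))
    plan += [(BENIGN, None, 0.0)] * config.n_benign

    samples: list[PlasmaSample] = []
    records: list[CohortRecord] = []
    child_seeds = ss.spawn(len(plan))
    n_mal_seen = n_ben_seen = 0
    for (label, stage, tf), child in zip(plan, child_seeds):
        if label == MALIGNANT:
            n_mal_seen += 1
            sid = f"{config.cohort_name}_mal_{n_mal_seen:03d}"
        else:
            n_ben_seen += 1
            sid = f"{config.cohort_name}_ben_{n_ben_seen:03d}"
        sample = simulate_plasma_sample(
            cpg_map, refs, tf, config.n_fragments,
            noise=config.conversion_noise,
            seed=int(child.generate_state(1)[0] % (2**31)),
            depletion_weight=config.depletion_weight,
            promoter_multiplier=config.promoter_multiplier,
            sample_id=sid, label=label,
        )
        samples.append(sample)

        is_mal = label == MALIGNANT
        mam_lat = 2.2 + (config.imaging_signal if is_mal else 0.0) + rng.normal(0.0, 1.0)
        us_lat = 2.2 + (config.ultrasound_signal if is_mal else 0.0) + rng.normal(0.0, 1.0)
        mean_lat = 0.5 * (mam_lat + us_lat)
        birads = "4a" if mean_lat < 2.5 else ("4b" if mean_lat < 3.5 else "4c")
        grade = None
        if is_mal:
            stage_ord = STAGES.index(stage)
            grade = int(np.clip(np.rint(1.0 + 0.6 * stage_ord + rng.normal(0.0, 0.7)), 1, 3))
        records.append(
            CohortRecord(
                sample_id=sid, label=label, cohort=config.cohort_name,
                birads_sub=birads,
                mammography_score=int(_ordinal_score(np.asarray(mam_lat))),
                ultrasound_score=int(_ordinal_score(np.asarray(us_lat))),
                stage=stage, grade=grade,
            )
        )
    return samples, records


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

#: desk-scale genome used for cohort studies: 2 x 150 kb sized so that 20k
#: fragments/sample gives roughly the 11x depth of a real plasma WGBS study
COHORT_GENOME = GenomeConfig(
    chromosomes=(("chr1", 150_000), ("chr2", 150_000)),
    background_cpg_rate=0.045,
    desert_fraction=0.30,
    desert_rate=0.0005,
    dense_block_bp=4_000,
    desert_block_bp=1_500,
    island_count=10,
    island_width_bp=1_000,
    island_density_multiplier=5.0,
)


@dataclass(frozen=True)
class StudyConfig:
    """Full two-cohort study: genome, tissue references, both cohorts."""

    genome: GenomeConfig = COHORT_GENOME
    n_tissue_malignant: int = 9
    n_tissue_benign: int = 10
    dmr_spec: DmrPlantSpec = DmrPlantSpec()
    discovery: CohortConfig = CohortConfig()
    validation: CohortConfig = CohortConfig(
        n_malignant=24, n_benign=25, cohort_name="validation"
    )


@dataclass
class StudyData:
    cpg_map: CpGMap
    tissues: list[TissueMethylome]
    truth: SimTruth
    discovery_samples: list[PlasmaSample]
    discovery_records: list[CohortRecord]
    validation_samples: list[PlasmaSample]
    validation_records: list[CohortRecord]


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyData:
    """Generate genome, tissue references, and both cohorts in one call."""
    config = config or StudyConfig()
    cpg_map = build_genome(config.genome, seed=seed)
    tissues, truth = simulate_tissue_methylomes(
        cpg_map, config.n_tissue_malignant, config.n_tissue_benign,
        config.dmr_spec, seed=seed,
    )
    disc_samples, disc_records = simulate_cohort(cpg_map, tissues, config.discovery, seed=seed)
    val_samples, val_records = simulate_cohort(
        cpg_map, tissues, config.validation, seed=seed + 104_729
    )
    return StudyData(
        cpg_map=cpg_map, tissues=tissues, truth=truth,
        discovery_samples=disc_samples, discovery_records=disc_records,
        validation_samples=val_samples, validation_records=val_records,
    )
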