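"""Synthetic genome model: ordered CpG sites with genomic context.

The genome is a desk-scale stand-in for the CpG landscape that matters to
cfDNA methylation analysis: CpGs occur in dense blocks separated by CpG
deserts, CpG islands sit preferentially at gene promoters, and every site
carries a region class (promoter / genic / intergenic).  Windowed GC content
and CpG density are carried alongside because cfDNA coverage biases are
functions of those two axes.

Coordinates are 0-based, half-open throughout (BED convention); a CpG site
occupies the 2 bp dinucleotide [pos, pos + 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

REGION_CLASSES = ("promoter", "genic", "intergenic")
PROMOTER, GENIC, INTERGENIC = 0, 1, 2


@dataclass(frozen=True)
class GenomeConfig:
    """Parameters of the synthetic CpG landscape.

    Rates are CpGs per bp.  The genome alternates "dense" blocks at
    ``background_cpg_rate`` with CpG deserts at ``desert_rate``; deserts are
    what gives gap-based candidate segmentation sub-chromosome granularity.
    CpG islands are contiguous runs of windows with the background rate
    multiplied by ``island_density_multiplier``, placed at promoters with
    probability ``promoter_island_prob`` (else uniformly at random).
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 5_000_000),
        ("chr2", 5_000_000),
    )
    window_bp: int = 500
    background_cpg_rate: float = 0.030
    desert_fraction: float = 0.30
    desert_rate: float = 0.0015
    dense_block_bp: int = 4_000
    desert_block_bp: int = 1_500
    island_count: int = 50
    island_width_bp: int = 1_000
    island_density_multiplier: float = 6.0
    gene_bp: int = 5_000
    promoter_bp: int = 1_000
    intergenic_bp: int = 4_000
    promoter_island_prob: float = 0.6

    def validate(self) -> None:
        if not self.chromosomes:
            raise ConfigError("at least one chromosome is required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length {length}")
        for key in ("background_cpg_rate", "desert_rate"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be positive")
        if not 0.0 <= self.desert_fraction < 1.0:
            raise ConfigError("desert_fraction must be in [0, 1)")
        if self.island_count < 0:
            raise ConfigError("island_count must be non-negative")
        if self.island_density_multiplier <= 0:
            raise ConfigError("island_density_multiplier must be positive")
        if min(self.gene_bp, self.promoter_bp, self.intergenic_bp) <= 0:
            raise ConfigError("gene/promoter/intergenic lengths must be positive")


@dataclass
class CpGMap:
    """Ordered CpG sites of a (synthetic or real) genome with window context.

    Sites are stored flat, sorted by (chromosome, position);
    ``site_offsets[c]:site_offsets[c+1]`` slices chromosome ``c``.  Window
    arrays are laid out the same way via ``window_offsets``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: np.ndarray  # int64, per chromosome
    site_pos: np.ndarray  # int64, position of the C of each CpG
    site_offsets: np.ndarray  # int64, len n_chrom + 1
    site_region: np.ndarray  # uint8 codes into REGION_CLASSES
    window_bp: int
    window_offsets: np.ndarray  # int64, len n_chrom + 1
    window_gc: np.ndarray  # float64 in [0, 1]
    window_cpg_density: np.ndarray  # CpGs per kb, from realized sites
    window_region: np.ndarray  # uint8, class of the window midpoint
    window_is_island: np.ndarray = field(default=None)  # bool

    # ------------------------------------------------------------------ basic
    @property
    def n_sites(self) -> int:
        return int(self.site_pos.shape[0])

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    @property
    def n_windows(self) -> int:
        return int(self.window_gc.shape[0])

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def site_chrom(self) -> np.ndarray:
        """Chromosome index per site (computed from offsets)."""
        return np.repeat(
            np.arange(self.n_chromosomes), np.diff(self.site_offsets)
        ).astype(np.int32)

    @property
    def window_chrom(self) -> np.ndarray:
        return np.repeat(
            np.arange(self.n_chromosomes), np.diff(self.window_offsets)
        ).astype(np.int32)

    @property
    def window_start(self) -> np.ndarray:
        counts = np.diff(self.window_offsets)
        starts = np.concatenate([np.arange(c) for c in counts]) if len(counts) else np.array([], int)
        return starts * self.window_bp

    def chrom_sites(self, chrom: int | str) -> np.ndarray:
        """Positions of all CpG sites on one chromosome."""
        c = self.chrom_index(chrom) if isinstance(chrom, str) else chrom
        return self.site_pos[self.site_offsets[c] : self.site_offsets[c + 1]]

    def sites_in(self, chrom: int | str, start: int, end: int) -> tuple[int, int]:
        """Global [lo, hi) site-index range with start <= pos < end."""
        c = self.chrom_index(chrom) if isinstance(chrom, str) else chrom
        base = self.site_offsets[c]
        pos = self.site_pos[base : self.site_offsets[c + 1]]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        return int(base) + lo, int(base) + hi

    def window_index(self, chrom: int | str, pos) -> np.ndarray:
        """Global window index for position(s) on one chromosome."""
        c = self.chrom_index(chrom) if isinstance(chrom, str) else chrom
        return self.window_offsets[c] + np.asarray(pos) // self.window_bp

    def validate(self) -> None:
        """Check the structural invariants; raises AssertionError on breach."""
        for c in range(self.n_chromosomes):
            pos = self.chrom_sites(c)
            if pos.size:
                assert pos[0] >= 0 and pos[-1] + 2 <= self.chrom_lengths[c]
                assert np.all(np.diff(pos) >= 2), "duplicate/overlapping CpG sites"
        assert self.site_region.shape == self.site_pos.shape
        assert np.all(self.site_region < len(REGION_CLASSES))
        assert np.all((self.window_gc >= 0) & (self.window_gc <= 1))


def region_class_of(positions: np.ndarray, config: GenomeConfig) -> np.ndarray:
    """Region class codes for positions under the periodic gene layout."""
    cycle = config.promoter_bp + config.gene_bp + config.intergenic_bp
    off = np.asarray(positions) % cycle
    out = np.full(off.shape, INTERGENIC, dtype=np.uint8)
    out[off < config.promoter_bp + config.gene_bp] = GENIC
    out[off < config.promoter_bp] = PROMOTER
    return out


def _block_labels(n_windows: int, config: GenomeConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean desert mask per window: alternating dense/desert blocks."""
    if config.desert_fraction == 0.0:
        return np.zeros(n_windows, dtype=bool)
    w = config.window_bp
    mean_dense = max(1, round(config.dense_block_bp / w))
    mean_desert = max(1, round(config.desert_block_bp / w))
    # rescale dense block length so the realized desert share matches config
    share = config.desert_fraction
    mean_dense = max(1, round(mean_desert * (1 - share) / share))
    mask = np.empty(n_windows, dtype=bool)
    i = 0
    desert = bool(rng.random() < share)
    while i < n_windows:
        mean = mean_desert if desert else mean_dense
        n = int(rng.geometric(1.0 / mean)) if mean > 1 else 1
        n = min(n, n_windows - i)
        mask[i : i + n] = desert
        i += n
        desert = not desert
    return mask


def build_genome(config: GenomeConfig | None = None, seed: int = 0) -> CpGMap:
    """Generate a :class:`CpGMap` from a :class:`GenomeConfig`.

    CpG sites are drawn on the even-position grid (enforcing the 2 bp
    footprint) with per-window Bernoulli probability 2 x local rate, so
    realized counts are binomial around ``rate x length``.  Deterministic for
    a given (config, seed).
    """
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    w = config.window_bp

    site_pos_parts: list[np.ndarray] = []
    site_offsets = [0]
    window_offsets = [0]
    win_rate_parts: list[np.ndarray] = []
    win_island_parts: list[np.ndarray] = []

    # choose island homes genome-wide, proportional to chromosome window counts
    n_windows_per_chrom = [max(1, length // w) for _, length in config.chromosomes]

    for c, (name, length) in enumerate(config.chromosomes):
        n_win = n_windows_per_chrom[c]
        desert = _block_labels(n_win, config, rng)
        rate = np.where(desert, config.desert_rate, config.background_cpg_rate)

        # islands: contiguous window runs at multiplied rate
        island_mask = np.zeros(n_win, dtype=bool)
        n_islands = round(config.island_count * n_win / sum(n_windows_per_chrom))
        island_wins = max(1, round(config.island_width_bp / w))
        if n_islands > 0:
            win_starts = np.arange(n_win) * w
            promoter_like = region_class_of(win_starts, config) == PROMOTER
            cand_prom = np.flatnonzero(promoter_like[: max(1, n_win - island_wins)])
            cand_any = np.arange(max(1, n_win - island_wins))
            for _ in range(n_islands):
                if cand_prom.size and rng.random() < config.promoter_island_prob:
                    j = int(rng.choice(cand_prom))
                else:
                    j = int(rng.choice(cand_any))
                island_mask[j : j + island_wins] = True
        rate = np.where(
            island_mask, config.background_cpg_rate * config.island_density_multiplier, rate
        )

        # Bernoulli on even positions; probability capped below saturation
        p_even = np.minimum(2.0 * rate, 0.9)
        n_even_per_win = w // 2
        p_flat = np.repeat(p_even, n_even_per_win)
        hits = rng.random(p_flat.shape[0]) < p_flat
        pos = 2 * np.flatnonzero(hits)
        pos = pos[pos + 2 <= length]
        site_pos_parts.append(pos.astype(np.int64))
        site_offsets.append(site_offsets[-1] + pos.shape[0])
        window_offsets.append(window_offsets[-1] + n_win)
        win_rate_parts.append(rate)
        win_island_parts.append(island_mask)

    site_pos = np.concatenate(site_pos_parts) if site_pos_parts else np.array([], np.int64)
    site_offsets_arr = np.asarray(site_offsets, dtype=np.int64)
    window_offsets_arr = np.asarray(window_offsets, dtype=np.int64)
    win_rate = np.concatenate(win_rate_parts)
    win_island = np.concatenate(win_island_parts)

    # realized window CpG density (per kb) and synthesized GC correlated with it
    counts = np.zeros(window_offsets_arr[-1], dtype=np.int64)
    for c in range(len(config.chromosomes)):
        pos = site_pos[site_offsets_arr[c] : site_offsets_arr[c + 1]]
        wi = window_offsets_arr[c] + pos // w
        np.add.at(counts, wi, 1)
    window_cpg_density = counts * (1000.0 / w)
    window_gc = np.clip(0.36 + 2.2 * win_rate + rng.normal(0.0, 0.02, win_rate.shape), 0.25, 0.78)

    site_region = region_class_of(site_pos, config)
    win_starts_all = np.concatenate(
        [np.arange(n) * w for n in np.diff(window_offsets_arr)]
    ) if window_offsets_arr[-1] else np.array([], np.int64)
    window_region = region_class_of(win_starts_all + w // 2, config)

    cpg_map = CpGMap(
        chrom_names=tuple(n for n, _ in config.chromosomes),
        chrom_lengths=np.asarray([l for _, l in config.chromosomes], dtype=np.int64),
        site_pos=site_pos,
        site_offsets=site_offsets_arr,
        site_region=site_region,
        window_bp=w,
        window_offsets=window_offsets_arr,
        window_gc=window_gc,
        window_cpg_density=window_cpg_density,
        window_region=window_region,
        window_is_island=win_island,
    )
    cpg_map.validate()
    return cpg_map
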