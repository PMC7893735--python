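"""cfDNA fragment bookkeeping: containers, size selection, DMR overlap.

Fragments are stored columnar (:class:`FragmentSet`) because a plasma sample
holds tens of thousands of them; :class:`Fragment` is a per-molecule view for
single-fragment work.  All coordinates are 0-based, half-open; a fragment's
methylation evidence is its ordered per-CpG binary calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .errors import EmptyInputError
from .genome import REGION_CLASSES, CpGMap

#: default size-selection window (bp) used to enrich the short ctDNA fraction
DEFAULT_SHORT_WINDOW = (90, 150)
#: library-prep retention bound: fragments shorter than this are kept
DEFAULT_MAX_LEN = 500


@dataclass(frozen=True)
class Fragment:
    """One sequenced cfDNA molecule with its per-CpG methylation calls."""

    chrom: str
    start: int
    end: int
    cpg_calls: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"fragment interval empty: [{self.start}, {self.end})")
        prev = self.start - 1
        for pos, state in self.cpg_calls:
            if not self.start <= pos < self.end:
                raise ValueError(f"CpG call at {pos} outside [{self.start}, {self.end})")
            if pos <= prev:
                raise ValueError("CpG call positions must be strictly increasing")
            if state not in (0, 1):
                raise ValueError("CpG call state must be 0 or 1")
            prev = pos

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """Columnar collection of fragments from one source (e.g. one plasma sample).

    CpG calls are stored flat with an offsets array, CSR-style:
    fragment ``i`` owns ``cpg_pos[cpg_offsets[i]:cpg_offsets[i+1]]``.
    """

    def __init__(self, chrom, start, end, cpg_offsets, cpg_pos, cpg_state, chrom_names):
        self.chrom = np.asarray(chrom, dtype=np.int32)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.cpg_offsets = np.asarray(cpg_offsets, dtype=np.int64)
        self.cpg_pos = np.asarray(cpg_pos, dtype=np.int64)
        self.cpg_state = np.asarray(cpg_state, dtype=np.uint8)
        self.chrom_names = tuple(chrom_names)
        if self.cpg_offsets.shape[0] != self.chrom.shape[0] + 1:
            raise ValueError("cpg_offsets must have n_fragments + 1 entries")

    # ------------------------------------------------------------- container
    def __len__(self) -> int:
        return int(self.chrom.shape[0])

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def n_calls_per_fragment(self) -> np.ndarray:
        return np.diff(self.cpg_offsets)

    @property
    def frag_index_per_call(self) -> np.ndarray:
        return np.repeat(np.arange(len(self)), self.n_calls_per_fragment)

    def __getitem__(self, i: int) -> Fragment:
        lo, hi = self.cpg_offsets[i], self.cpg_offsets[i + 1]
        calls = tuple(
            (int(p), int(s)) for p, s in zip(self.cpg_pos[lo:hi], self.cpg_state[lo:hi])
        )
        return Fragment(
            chrom=self.chrom_names[self.chrom[i]],
            start=int(self.start[i]),
            end=int(self.end[i]),
            cpg_calls=calls,
        )

    def __iter__(self) -> Iterator[Fragment]:
        return (self[i] for i in range(len(self)))

    def subset(self, index) -> "FragmentSet":
        """New FragmentSet with the selected fragments, order preserved."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        counts = self.n_calls_per_fragment[index]
        new_offsets = np.concatenate([[0], np.cumsum(counts)])
        take = np.concatenate(
            [np.arange(self.cpg_offsets[i], self.cpg_offsets[i + 1]) for i in index]
        ) if index.size else np.array([], dtype=np.int64)
        return FragmentSet(
            self.chrom[index], self.start[index], self.end[index],
            new_offsets, self.cpg_pos[take], self.cpg_state[take], self.chrom_names,
        )

    @classmethod
    def from_fragments(cls, fragments: Sequence[Fragment], chrom_names=None) -> "FragmentSet":
        if chrom_names is None:
            seen = []
            for f in fragments:
                if f.chrom not in seen:
                    seen.append(f.chrom)
            chrom_names = tuple(seen)
        lookup = {c: i for i, c in enumerate(chrom_names)}
        chrom = [lookup[f.chrom] for f in fragments]
        start = [f.start for f in fragments]
        end = [f.end for f in fragments]
        offsets = np.concatenate([[0], np.cumsum([len(f.cpg_calls) for f in fragments])])
        pos = [p for f in fragments for p, _ in f.cpg_calls]
        state = [s for f in fragments for _, s in f.cpg_calls]
        return cls(chrom, start, end, offsets, pos, state, chrom_names)


@dataclass
class SizeProfile:
    """1-bp resolution fragment length histogram with summary statistics."""

    bin_length: np.ndarray  # bp value of each occupied range [0 .. max]
    count: np.ndarray
    mode_bp: int
    fraction_short: float
    short_window: tuple[int, int]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_fragments_by_length(
    fragments: FragmentSet,
    max_len_bp: int = DEFAULT_MAX_LEN,
    short_window: tuple[int, int] | None = None,
) -> FragmentSet:
    """Length filtering: keep fragments with length strictly below ``max_len_bp``.

    If ``short_window=(lo, hi)`` is given, additionally keep only lengths in
    the closed window [lo, hi] — the size-selection step that enriches the
    shorter tumor-derived fraction.  Idempotent; order preserved.
    """
    if max_len_bp <= 0:
        raise ValueError("max_len_bp must be positive")
    lengths = fragments.lengths
    mask = lengths < max_len_bp
    if short_window is not None:
        lo, hi = short_window
        if lo > hi:
            raise ValueError(f"short_window lower bound {lo} exceeds upper bound {hi}")
        mask &= (lengths >= lo) & (lengths <= hi)
    return fragments.subset(mask)


def size_profile(
    fragments: FragmentSet, short_window: tuple[int, int] = DEFAULT_SHORT_WINDOW
) -> SizeProfile:
    """Fragment length histogram at 1-bp bins.

    The mode is the smallest length among maximal bins (deterministic
    tie-break); ``fraction_short`` is the share of fragments inside the
    size-selection window.
    """
    if len(fragments) == 0:
        raise EmptyInputError("size_profile requires at least one fragment")
    lengths = np.asarray(fragments.lengths)
    counts = np.bincount(lengths)
    mode_bp = int(np.argmax(counts))  # argmax returns first (smallest) maximal bin
    lo, hi = short_window
    frac = float(np.mean((lengths >= lo) & (lengths <= hi)))
    return SizeProfile(
        bin_length=np.arange(counts.shape[0]),
        count=counts,
        mode_bp=mode_bp,
        fraction_short=frac,
        short_window=(lo, hi),
    )


def _dmr_arrays(dmrs, chrom_names):
    """Per-chromosome sorted (starts, ends, global index); validates layout."""
    lookup = {c: i for i, c in enumerate(chrom_names)}
    per_chrom: dict[int, list[tuple[int, int, int]]] = {}
    last: dict[int, tuple[int, int]] = {}
    for gi, d in enumerate(dmrs):
        c = lookup.get(d.chrom if isinstance(d.chrom, str) else chrom_names[d.chrom])
        if c is None:
            continue  # DMR on a chromosome absent from this fragment set
        if c in last and d.start < last[c]:
            raise ValueError("DMRs must be sorted and non-overlapping per chromosome")
        last[c] = d.end
        per_chrom.setdefault(c, []).append((d.start, d.end, gi))
    out = {}
    for c, triples in per_chrom.items():
        arr = np.asarray(triples, dtype=np.int64)
        out[c] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


def assign_fragments_to_dmrs(fragments: FragmentSet, dmrs) -> np.ndarray:
    """Assign each fragment to at most one DMR by CpG containment.

    A fragment belongs to a DMR iff at least one of its CpG calls lies inside
    the DMR's half-open interval; when its calls span several DMRs it goes to
    the one holding the most calls (ties to the leftmost).  Returns an int
    array: DMR index per fragment, -1 when unassigned.
    """
    dmrs = list(dmrs)
    by_chrom = _dmr_arrays(dmrs, fragments.chrom_names)
    n_frag = len(fragments)
    assignment = np.full(n_frag, -1, dtype=np.int64)
    if n_frag == 0 or not dmrs:
        return assignment

    frag_per_call = fragments.frag_index_per_call
    call_chrom = fragments.chrom[frag_per_call]
    call_dmr = np.full(fragments.cpg_pos.shape[0], -1, dtype=np.int64)
    for c, (starts, ends, gidx) in by_chrom.items():
        sel = call_chrom == c
        pos = fragments.cpg_pos[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        vals = np.where(inside, gidx[np.clip(j, 0, None)], -1)
        call_dmr[sel] = vals

    valid = call_dmr >= 0
    if not valid.any():
        return assignment
    fi = frag_per_call[valid]
    di = call_dmr[valid]
    n_dmr = len(dmrs)
    key = fi * n_dmr + di
    uk, cnt = np.unique(key, return_counts=True)
    ufrag, udmr = uk // n_dmr, uk % n_dmr
    order = np.lexsort((udmr, -cnt, ufrag))  # per fragment: most calls, then leftmost
    ufrag, udmr = ufrag[order], udmr[order]
    first = np.concatenate([[True], ufrag[1:] != ufrag[:-1]])
    assignment[ufrag[first]] = udmr[first]
    return assignment


def fragments_by_dmr(fragments: FragmentSet, dmrs) -> list[np.ndarray]:
    """Per-DMR lists of fragment indices (wrapper over assignment vector)."""
    assignment = assign_fragments_to_dmrs(fragments, dmrs)
    return [np.flatnonzero(assignment == i) for i in range(len(list(dmrs)))]


def enrichment_score(sample, dmrs, per_million: bool = False) -> float:
    """Mean number of assigned fragments per DMR (cfDNA enrichment score).

    ``sample`` may be a FragmentSet or anything with a ``.fragments``
    attribute.  With ``per_million=True`` the score is additionally divided
    by the total fragment count and scaled by 1e6.
    """
    fragments = getattr(sample, "fragments", sample)
    dmrs = list(dmrs)
    if not dmrs:
        raise EmptyInputError("enrichment_score requires at least one DMR")
    assignment = assign_fragments_to_dmrs(fragments, dmrs)
    score = float(np.sum(assignment >= 0)) / len(dmrs)
    if per_million:
        total = len(fragments)
        score = score / total * 1e6 if total else 0.0
    return score


@dataclass
class CoverageProfile:
    """Windowed coverage summary against genomic context."""

    mean_per_kb: dict[str, float]  # region class -> mean fragments per kb
    density_correlation: float  # Pearson r of window fragment count vs CpG density
    density_correlation_p: float


def coverage_by_region_class(sample, cpg_map: CpGMap) -> CoverageProfile:
    """Fragment coverage by region class and its relation to CpG density.

    Fragments are binned into map windows by midpoint; per class we report
    mean fragments per kb, plus the Pearson correlation between window
    fragment count and window CpG density across all windows.
    """
    fragments = getattr(sample, "fragments", sample)
    if len(fragments) == 0:
        raise EmptyInputError("coverage profiling requires a non-empty sample")
    counts = np.zeros(cpg_map.n_windows, dtype=np.int64)
    mid = (fragments.start + fragments.end) // 2
    for c in range(cpg_map.n_chromosomes):
        sel = fragments.chrom == c
        if not sel.any():
            continue
        wi = cpg_map.window_offsets[c] + mid[sel] // cpg_map.window_bp
        wi = np.clip(wi, cpg_map.window_offsets[c], cpg_map.window_offsets[c + 1] - 1)
        np.add.at(counts, wi, 1)
    kb = cpg_map.window_bp / 1000.0
    mean_per_kb = {}
    for code, name in enumerate(REGION_CLASSES):
        sel = cpg_map.window_region == code
        mean_per_kb[name] = float(counts[sel].mean() / kb) if sel.any() else float("nan")
    r, p = stats.pearsonr(counts, cpg_map.window_cpg_density)
    return CoverageProfile(mean_per_kb=mean_per_kb, density_correlation=float(r),
                           density_correlation_p=float(p))
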