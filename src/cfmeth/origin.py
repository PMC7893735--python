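"""Fragment-level origin inference and per-DMR malignant ratios.

Each cfDNA fragment carries a joint methylation pattern over the CpGs it
covers.  Within a DMR, the malignant and benign tissue groups define
per-CpG reference methylation probabilities (group means, clamped away from
0/1); the fragment's log-likelihood under each origin is an
independent-Bernoulli product over its covered CpGs.  Fragments are
classified malignant / benign / ambiguous by the log-likelihood ratio
against a symmetric threshold, and a sample's per-DMR "malignant ratio" is
the fraction of classified fragments called malignant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, InsufficientReplicatesError
from .fragments import (
    DEFAULT_MAX_LEN,
    DEFAULT_SHORT_WINDOW,
    Fragment,
    FragmentSet,
    assign_fragments_to_dmrs,
    filter_fragments_by_length,
)
from .genome import CpGMap

MALIGNANT, BENIGN, AMBIGUOUS, UNINFORMATIVE = (
    "malignant", "benign", "ambiguous", "uninformative",
)
_CODES = {MALIGNANT: 1, BENIGN: -1, AMBIGUOUS: 0, UNINFORMATIVE: -2}


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

@dataclass
class PanelEntry:
    """Per-DMR reference: aligned CpG positions and group methylation probs."""

    dmr_id: str
    chrom: str
    start: int
    end: int
    positions: np.ndarray  # bp positions of CpG sites inside the DMR
    p_mal: np.ndarray  # clamped into (0, 1)
    p_ben: np.ndarray


@dataclass
class ReferencePanel:
    """Reference methylation probabilities for a set of DMRs."""

    entries: list[PanelEntry]
    epsilon: float

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> PanelEntry:
        return self.entries[i]

    @property
    def dmr_ids(self) -> list[str]:
        return [e.dmr_id for e in self.entries]


def build_reference_panel(
    dmrs, methylomes, cpg_map: CpGMap, epsilon: float = 0.01
) -> ReferencePanel:
    """Group-mean reference probabilities per DMR, clamped to [eps, 1 - eps].

    The clamp keeps every per-CpG log-likelihood finite.  DMRs without CpG
    sites are excluded with a warning.
    """
    if not 0.0 < epsilon <= 0.1:
        raise ConfigError(f"epsilon must be in (0, 0.1], got {epsilon}")
    mal = [m for m in methylomes if m.group == MALIGNANT]
    ben = [m for m in methylomes if m.group == BENIGN]
    if not mal or not ben:
        raise InsufficientReplicatesError("both tissue groups are required for the panel")
    mal_mean = np.mean([m.beta for m in mal], axis=0)
    ben_mean = np.mean([m.beta for m in ben], axis=0)
    entries: list[PanelEntry] = []
    for d in dmrs:
        lo, hi = cpg_map.sites_in(d.chrom, d.start, d.end)
        if hi == lo:
            warnings.warn(f"DMR {d.chrom}:{d.start}-{d.end} has no CpG sites; excluded",
                          stacklevel=2)
            continue
        entries.append(
            PanelEntry(
                dmr_id=f"{d.chrom}:{d.start}-{d.end}",
                chrom=d.chrom, start=d.start, end=d.end,
                positions=cpg_map.site_pos[lo:hi].copy(),
                p_mal=np.clip(mal_mean[lo:hi], epsilon, 1.0 - epsilon),
                p_ben=np.clip(ben_mean[lo:hi], epsilon, 1.0 - epsilon),
            )
        )
    return ReferencePanel(entries=entries, epsilon=epsilon)


def panel_entry_from_probs(chrom, start, end, positions, p_mal, p_ben,
                           epsilon: float = 0.01) -> PanelEntry:
    """Build a panel entry directly from probabilities (handy for tests)."""
    return PanelEntry(
        dmr_id=f"{chrom}:{start}-{end}", chrom=chrom, start=start, end=end,
        positions=np.asarray(positions, dtype=np.int64),
        p_mal=np.clip(np.asarray(p_mal, float), epsilon, 1 - epsilon),
        p_ben=np.clip(np.asarray(p_ben, float), epsilon, 1 - epsilon),
    )


# ---------------------------------------------------------------------------
# per-fragment likelihoods
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioConfig:
    """Knobs of origin inference and ratio aggregation."""

    llr_threshold: float = log(2.0)
    min_cpgs_per_fragment: int = 3
    min_fragments: int = 5
    estimator: str = "hard"  # "hard" (count ratio) | "posterior" (mean weight)
    apply_size_selection: bool = True
    max_len_bp: int = DEFAULT_MAX_LEN
    short_window: tuple[int, int] = DEFAULT_SHORT_WINDOW

    def validate(self) -> None:
        if self.llr_threshold < 0:
            raise ConfigError("llr_threshold must be non-negative")
        if self.min_cpgs_per_fragment < 1:
            raise ConfigError("min_cpgs_per_fragment must be >= 1")
        if self.estimator not in ("hard", "posterior"):
            raise ConfigError(f"unknown estimator {self.estimator!r}")


def _informative_calls(fragment: Fragment, entry: PanelEntry):
    """Indices into entry arrays + states, for calls inside the DMR."""
    idx, states = [], []
    for pos, state in fragment.cpg_calls:
        if entry.start <= pos < entry.end:
            j = int(np.searchsorted(entry.positions, pos))
            if j < entry.positions.shape[0] and entry.positions[j] == pos:
                idx.append(j)
                states.append(state)
    return np.asarray(idx, dtype=np.int64), np.asarray(states, dtype=np.float64)


def fragment_log_likelihood(fragment: Fragment, entry: PanelEntry) -> tuple[float, float]:
    """(ll_malignant, ll_benign) of the fragment's joint methylation pattern.

    Independent Bernoulli over the fragment's CpG calls that fall inside the
    DMR; both values are finite thanks to the panel's probability clamp.
    """
    idx, s = _informative_calls(fragment, entry)
    lls = []
    for p in (entry.p_mal[idx], entry.p_ben[idx]):
        lls.append(float(np.sum(s * np.log(p) + (1.0 - s) * np.log1p(-p))))
    return lls[0], lls[1]


def classify_fragment(
    fragment: Fragment,
    entry: PanelEntry,
    llr_threshold: float = log(2.0),
    min_cpgs: int = 3,
) -> str:
    """Classify one fragment's origin by its log-likelihood ratio.

    Returns "malignant" (llr >= +threshold), "benign" (llr <= -threshold),
    "ambiguous" in between, or "uninformative" when fewer than ``min_cpgs``
    of its calls lie inside the DMR (such fragments are excluded upstream,
    not an error).
    """
    idx, _ = _informative_calls(fragment, entry)
    if idx.shape[0] < min_cpgs:
        return UNINFORMATIVE
    ll_mal, ll_ben = fragment_log_likelihood(fragment, entry)
    llr = ll_mal - ll_ben
    if llr >= llr_threshold:
        return MALIGNANT
    if llr <= -llr_threshold:
        return BENIGN
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# bulk classification and ratios
# ---------------------------------------------------------------------------

def _classify_bulk(fragments: FragmentSet, panel: ReferencePanel, config: RatioConfig):
    """Vectorized classification of a fragment set against a panel.

    Returns (assignment, label_code, llr, n_informative) per fragment, where
    assignment is the panel-entry index (-1 unassigned) and label codes are
    1 malignant / -1 benign / 0 ambiguous / -2 uninformative.
    """
    assignment = assign_fragments_to_dmrs(fragments, panel.entries)
    n = len(fragments)
    llr = np.zeros(n)
    n_inf = np.zeros(n, dtype=np.int64)
    frag_per_call = fragments.frag_index_per_call
    call_assign = assignment[frag_per_call] if frag_per_call.size else frag_per_call
    for i, entry in enumerate(panel.entries):
        mask = (call_assign == i) & (fragments.cpg_pos >= entry.start) \
            & (fragments.cpg_pos < entry.end)
        if not mask.any():
            continue
        pos = fragments.cpg_pos[mask]
        s = fragments.cpg_state[mask].astype(np.float64)
        j = np.searchsorted(entry.positions, pos)
        ok = (j < entry.positions.shape[0]) & (entry.positions[np.clip(j, 0, None)] == pos)
        j, s = j[ok], s[ok]
        fi = frag_per_call[mask][ok]
        contrib = (
            s * (np.log(entry.p_mal[j]) - np.log(entry.p_ben[j]))
            + (1.0 - s) * (np.log1p(-entry.p_mal[j]) - np.log1p(-entry.p_ben[j]))
        )
        np.add.at(llr, fi, contrib)
        np.add.at(n_inf, fi, 1)
    labels = np.full(n, _CODES[UNINFORMATIVE], dtype=np.int8)
    informative = (assignment >= 0) & (n_inf >= config.min_cpgs_per_fragment)
    labels[informative & (np.abs(llr) < config.llr_threshold)] = _CODES[AMBIGUOUS]
    labels[informative & (llr >= config.llr_threshold)] = _CODES[MALIGNANT]
    labels[informative & (llr <= -config.llr_threshold)] = _CODES[BENIGN]
    return assignment, labels, llr, n_inf


def _prepare_fragments(sample, config: RatioConfig) -> FragmentSet:
    fragments = getattr(sample, "fragments", sample)
    if config.apply_size_selection:
        fragments = filter_fragments_by_length(
            fragments, config.max_len_bp, config.short_window
        )
    return fragments


def sample_ratios(sample, panel: ReferencePanel, config: RatioConfig | None = None):
    """Per-DMR (ratio, n_classified) for one plasma sample.

    ratio is NaN (missing) where fewer than ``min_fragments`` fragments were
    classified; missingness is a value, not an error.
    """
    config = config or RatioConfig()
    config.validate()
    fragments = _prepare_fragments(sample, config)
    m = len(panel)
    ratios = np.full(m, np.nan)
    counts = np.zeros(m, dtype=np.int64)
    if len(fragments) == 0:
        return ratios, counts
    assignment, labels, llr, n_inf = _classify_bulk(fragments, panel, config)
    informative = labels != _CODES[UNINFORMATIVE]
    for i in range(m):
        sel = (assignment == i) & informative
        if config.estimator == "hard":
            n_mal = int(np.sum(labels[sel] == _CODES[MALIGNANT]))
            n_ben = int(np.sum(labels[sel] == _CODES[BENIGN]))
            counts[i] = n_mal + n_ben
            if counts[i] >= config.min_fragments:
                ratios[i] = n_mal / counts[i]
        else:  # posterior-weighted mixture estimate
            counts[i] = int(sel.sum())
            if counts[i] >= config.min_fragments:
                w = 1.0 / (1.0 + np.exp(-llr[sel]))
                ratios[i] = float(w.mean())
    return ratios, counts


def malignant_ratio(sample, dmr, panel: ReferencePanel,
                    config: RatioConfig | None = None) -> float:
    """Malignant ratio of one sample in one DMR (NaN when under-covered)."""
    dmr_id = f"{dmr.chrom}:{dmr.start}-{dmr.end}" if hasattr(dmr, "chrom") else str(dmr)
    try:
        i = panel.dmr_ids.index(dmr_id)
    except ValueError:
        raise KeyError(f"DMR {dmr_id} not in panel") from None
    ratios, _ = sample_ratios(sample, panel, config)
    return float(ratios[i])


# ---------------------------------------------------------------------------
# marker profiles
# ---------------------------------------------------------------------------

@dataclass
class MarkerProfile:
    """One sample's per-DMR malignant ratios and informative counts."""

    sample_id: str
    ratios: dict[str, float]
    counts: dict[str, int]
    missing: frozenset[str]


@dataclass
class MarkerProfileSet:
    """Cohort-level ratio matrix: the classifier's feature space."""

    ratios: pd.DataFrame  # samples x DMR ids, missing entries imputed
    counts: pd.DataFrame
    missing: pd.DataFrame  # bool mask of originally-missing entries
    impute_values: pd.Series  # per-DMR value used for imputation

    @property
    def profiles(self) -> list[MarkerProfile]:
        out = []
        for sid in self.ratios.index:
            miss = frozenset(self.missing.columns[self.missing.loc[sid]])
            out.append(
                MarkerProfile(
                    sample_id=sid,
                    ratios=self.ratios.loc[sid].to_dict(),
                    counts=self.counts.loc[sid].astype(int).to_dict(),
                    missing=miss,
                )
            )
        return out


def build_marker_profiles(
    samples, panel: ReferencePanel,
    config: RatioConfig | None = None,
    max_missing_fraction: float = 0.5,
    impute_values: pd.Series | None = None,
) -> MarkerProfileSet:
    """Per-sample, per-DMR malignant-ratio matrix with missingness handling.

    DMRs missing in more than ``max_missing_fraction`` of samples are dropped
    with a warning.  Remaining missing entries are imputed with the per-DMR
    benign-group median (samples labelled "benign"; overall median when no
    labels are available).  Pass ``impute_values`` (e.g. from the discovery
    cohort) to impute a held-out cohort without touching its labels.
    """
    config = config or RatioConfig()
    ids = panel.dmr_ids
    rows, crows, sids, labels = [], [], [], []
    for s in samples:
        r, c = sample_ratios(s, panel, config)
        rows.append(r)
        crows.append(c)
        sids.append(getattr(s, "sample_id", f"s{len(sids)}"))
        labels.append(getattr(s, "label", None))
    ratios = pd.DataFrame(rows, index=sids, columns=ids)
    counts = pd.DataFrame(crows, index=sids, columns=ids)
    missing = ratios.isna()

    drop = missing.mean(axis=0) > max_missing_fraction
    if drop.any():
        warnings.warn(
            f"dropping {int(drop.sum())} DMR(s) missing in more than "
            f"{max_missing_fraction:.0%} of samples", stacklevel=2,
        )
        keep = [c for c in ids if not drop[c]]
        ratios, counts, missing = ratios[keep], counts[keep], missing[keep]

    if impute_values is None:
        benign_rows = [i for i, lab in enumerate(labels) if lab == BENIGN]
        ref = ratios.iloc[benign_rows] if benign_rows else ratios
        impute_values = ref.median(axis=0, skipna=True).fillna(0.0)
    else:
        impute_values = impute_values.reindex(ratios.columns).fillna(0.0)
    ratios = ratios.fillna(impute_values)
    return MarkerProfileSet(
        ratios=ratios, counts=counts, missing=missing, impute_values=impute_values
    )
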