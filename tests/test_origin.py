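"""Origin inference: reference panels, Bernoulli-product likelihoods,
classification against a brute-force oracle, ratios and marker profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfmeth import (
    ConfigError,
    Fragment,
    FragmentSet,
    InsufficientReplicatesError,
    RatioConfig,
    ReferencePanel,
    build_marker_profiles,
    build_reference_panel,
    classify_fragment,
    fragment_log_likelihood,
    panel_entry_from_probs,
    sample_ratios,
    simulate_plasma_sample,
)
from cfmeth.dmr import Region

from conftest import make_methylomes, make_toy_map


def entry(p_mal, p_ben, spacing=20, start=0):
    k = len(p_mal)
    positions = [start + spacing * (i + 1) for i in range(k)]
    return panel_entry_from_probs(
        "chr1", start, start + spacing * (k + 1), positions, p_mal, p_ben
    )


def fragment_for(e, states):
    calls = tuple((int(p), int(s)) for p, s in zip(e.positions, states))
    return Fragment(e.chrom, e.start, e.end, calls)


# -------------------------------------------------------------------- panel

def test_panel_clamps_and_averages():
    m = make_toy_map({"chr1": [100, 200]})
    tissues = make_methylomes(2, [1.0, 0.2], [0.0, 0.4])
    tissues[0].beta[1] = 0.2
    tissues[1].beta[1] = 0.4  # malignant group betas {0.2, 0.4} at site 1
    panel = build_reference_panel([Region("chr1", 0, 300)], tissues, m, epsilon=0.01)
    e = panel[0]
    assert e.p_mal[0] == pytest.approx(0.99)  # clamp of mean 1.0
    assert e.p_ben[0] == pytest.approx(0.01)
    assert e.p_mal[1] == pytest.approx(0.3)


def test_panel_requires_both_groups_and_sites():
    m = make_toy_map({"chr1": [100, 200]})
    only_ben = [t for t in make_methylomes(2, 0.5, 0.5) if t.group == "benign"]
    with pytest.raises(InsufficientReplicatesError):
        build_reference_panel([Region("chr1", 0, 300)], only_ben, m)
    tissues = make_methylomes(2, 0.5, 0.5)
    with pytest.warns(UserWarning, match="no CpG sites"):
        panel = build_reference_panel(
            [Region("chr1", 0, 300), Region("chr1", 5000, 6000)], tissues, m
        )
    assert len(panel) == 1
    with pytest.raises(ConfigError):
        build_reference_panel([Region("chr1", 0, 300)], tissues, m, epsilon=0.5)


# -------------------------------------------------------------- likelihoods

def test_log_likelihood_hand_computed():
    e = entry([0.9, 0.9, 0.9], [0.5, 0.5, 0.5])
    ll_mal, ll_ben = fragment_log_likelihood(fragment_for(e, (1, 1, 1)), e)
    assert ll_mal == pytest.approx(3 * math.log(0.9))
    assert ll_ben == pytest.approx(3 * math.log(0.5))


def test_symmetric_reference_gives_equal_likelihoods():
    e = entry([0.5] * 3, [0.5] * 3)
    ll_mal, ll_ben = fragment_log_likelihood(fragment_for(e, (1, 0, 1)), e)
    assert ll_mal == ll_ben == pytest.approx(3 * math.log(0.5))
    assert classify_fragment(fragment_for(e, (1, 0, 1)), e) == "ambiguous"


def test_hypomethylated_fragment_called_malignant():
    e = entry([0.1] * 4, [0.9] * 4)
    f = fragment_for(e, (0, 0, 0, 0))
    ll_mal, ll_ben = fragment_log_likelihood(f, e)
    assert ll_mal - ll_ben == pytest.approx(4 * math.log(9))
    assert classify_fragment(f, e) == "malignant"


def test_uninformative_below_min_cpgs():
    e = entry([0.1] * 4, [0.9] * 4)
    f = Fragment(e.chrom, e.start, e.end, ((int(e.positions[0]), 0),))
    assert classify_fragment(f, e, min_cpgs=3) == "uninformative"


@given(
    st.lists(st.floats(min_value=0.02, max_value=0.98), min_size=2, max_size=5),
    st.data(),
)
@settings(max_examples=40, deadline=None)
def test_llr_antisymmetric_under_group_swap(p_mal, data):
    k = len(p_mal)
    p_ben = data.draw(st.lists(st.floats(0.02, 0.98), min_size=k, max_size=k))
    states = data.draw(st.lists(st.integers(0, 1), min_size=k, max_size=k))
    e = entry(p_mal, p_ben)
    e_swapped = entry(p_ben, p_mal)
    f = fragment_for(e, states)
    a_mal, a_ben = fragment_log_likelihood(f, e)
    b_mal, b_ben = fragment_log_likelihood(f, e_swapped)
    assert a_mal - a_ben == pytest.approx(-(b_mal - b_ben))


def test_classification_matches_exhaustive_oracle():
    """Every pattern at k <= 5 CpGs agrees exactly with an explicit-product
    enumeration of both likelihoods, over random reference panels."""
    rng = np.random.default_rng(2024)
    threshold = math.log(2.0)
    for _ in range(50):
        k = int(rng.integers(2, 6))
        p_mal = rng.uniform(0.05, 0.95, k)
        p_ben = rng.uniform(0.05, 0.95, k)
        e = entry(list(p_mal), list(p_ben))
        for pattern in range(2**k):
            states = [(pattern >> i) & 1 for i in range(k)]
            lm = lb = 1.0
            for s, pm, pb in zip(states, e.p_mal, e.p_ben):
                lm *= pm if s else 1.0 - pm
                lb *= pb if s else 1.0 - pb
            llr = math.log(lm) - math.log(lb)
            expected = (
                "malignant" if llr >= threshold
                else "benign" if llr <= -threshold
                else "ambiguous"
            )
            got = classify_fragment(fragment_for(e, states), e, min_cpgs=1)
            assert got == expected, f"pattern {states} p_mal={p_mal} p_ben={p_ben}"


# ------------------------------------------------------------------- ratios

IDEAL = RatioConfig(apply_size_selection=False, min_cpgs_per_fragment=2, min_fragments=1)


def test_ratio_extremes():
    e = entry([0.05] * 4, [0.95] * 4)
    panel = ReferencePanel([e], epsilon=0.01)
    all_mal = FragmentSet.from_fragments(
        [fragment_for(e, (0, 0, 0, 0)) for _ in range(6)], ("chr1",)
    )
    ratios, counts = sample_ratios(all_mal, panel, IDEAL)
    assert ratios[0] == 1.0 and counts[0] == 6
    all_ben = FragmentSet.from_fragments(
        [fragment_for(e, (1, 1, 1, 1)) for _ in range(6)], ("chr1",)
    )
    ratios, _ = sample_ratios(all_ben, panel, IDEAL)
    assert ratios[0] == 0.0


def test_ratio_missing_when_undercovered():
    e = entry([0.05] * 4, [0.95] * 4)
    panel = ReferencePanel([e], epsilon=0.01)
    fs = FragmentSet.from_fragments([fragment_for(e, (0, 0, 0, 0))], ("chr1",))
    cfg = RatioConfig(apply_size_selection=False, min_cpgs_per_fragment=2, min_fragments=5)
    ratios, counts = sample_ratios(fs, panel, cfg)
    assert np.isnan(ratios[0]) and counts[0] == 1


def test_posterior_estimator_bounded():
    e = entry([0.1] * 4, [0.9] * 4)
    panel = ReferencePanel([e], epsilon=0.01)
    fs = FragmentSet.from_fragments(
        [fragment_for(e, (0, 0, 1, 1)), fragment_for(e, (0, 0, 0, 0))], ("chr1",)
    )
    cfg = RatioConfig(apply_size_selection=False, min_cpgs_per_fragment=2,
                      min_fragments=1, estimator="posterior")
    ratios, _ = sample_ratios(fs, panel, cfg)
    assert 0.0 <= ratios[0] <= 1.0


# ------------------------------------------------------------------ profiles

def test_profiles_complete_matrix_and_imputation(cohort_map, tissue_refs, hypo_panel):
    tf = [0.0, 0.0, 0.1]
    samples = []
    for i, t in enumerate(tf):
        s = simulate_plasma_sample(
            cohort_map, tissue_refs, t, 8_000, seed=40 + i,
            sample_id=f"p{i}", label="benign" if t == 0 else "malignant",
        )
        samples.append(s)
    mps = build_marker_profiles(samples, hypo_panel, max_missing_fraction=1.0)
    assert mps.ratios.shape == (3, len(hypo_panel))
    assert not mps.ratios.isna().any().any()  # everything defined or imputed
    # imputed entries equal the benign median of their column
    for sid in mps.ratios.index:
        for col in mps.missing.columns[mps.missing.loc[sid]]:
            assert mps.ratios.loc[sid, col] == pytest.approx(mps.impute_values[col])


def test_sparse_dmr_dropped_with_warning(cohort_map, tissue_refs, hypo_panel):
    samples = [
        simulate_plasma_sample(cohort_map, tissue_refs, 0.0, 300, seed=50 + i,
                               sample_id=f"p{i}", label="benign")
        for i in range(3)
    ]
    with pytest.warns(UserWarning, match="dropping"):
        mps = build_marker_profiles(samples, hypo_panel)
    assert mps.ratios.shape[1] < len(hypo_panel)


def test_null_cohort_ratios_stay_low(cohort_map, tissue_refs, hypo_panel):
    samples = [
        simulate_plasma_sample(cohort_map, tissue_refs, 0.0, 8_000, seed=60 + i,
                               sample_id=f"b{i}", label="benign")
        for i in range(4)
    ]
    mps = build_marker_profiles(samples, hypo_panel, max_missing_fraction=1.0)
    assert mps.ratios.to_numpy().mean() < 0.1
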