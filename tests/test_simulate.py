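"""Generator behaviour: planted tissue signal, fragment lengths, plasma
mixtures, cohort composition."""

import numpy as np
import pytest

from cfmeth import (
    CohortConfig,
    ConfigError,
    DmrPlantSpec,
    PlantedDMR,
    sample_fragment_length,
    simulate_cohort,
    simulate_plasma_sample,
    simulate_tissue_methylomes,
)
from cfmeth.simulate import NONTUMOR_LENGTHS, TUMOR_LENGTHS

from conftest import make_methylomes, make_toy_map


# ------------------------------------------------------------------ tissues

def test_zero_dmr_config_plants_nothing(cohort_map):
    spec = DmrPlantSpec(n_hyper=0, n_hypo=0)
    tissues, truth = simulate_tissue_methylomes(cohort_map, dmr_spec=spec, seed=1)
    assert truth.planted_dmrs == []
    mal = np.mean([t.beta for t in tissues if t.group == "malignant"], axis=0)
    ben = np.mean([t.beta for t in tissues if t.group == "benign"], axis=0)
    # noise only: group means agree closely everywhere
    assert np.max(np.abs(mal - ben)) < 0.15
    assert np.abs(mal - ben).mean() < 0.03


def test_single_hypo_dmr_has_planted_effect_size(cohort_map):
    spec = DmrPlantSpec(n_hyper=0, n_hypo=1, delta_hypo=0.4)
    tissues, truth = simulate_tissue_methylomes(cohort_map, dmr_spec=spec, seed=2)
    (d,) = truth.planted_dmrs
    assert d.direction == "hypo"
    lo, hi = cohort_map.sites_in(d.chrom, d.start, d.end)
    mal = np.mean([t.beta[lo:hi] for t in tissues if t.group == "malignant"])
    ben = np.mean([t.beta[lo:hi] for t in tissues if t.group == "benign"])
    assert -0.45 <= mal - ben <= -0.35


def test_beta_values_bounded_and_deterministic(cohort_map):
    t1, _ = simulate_tissue_methylomes(cohort_map, seed=5)
    t2, _ = simulate_tissue_methylomes(cohort_map, seed=5)
    for a, b in zip(t1, t2):
        assert np.array_equal(a.beta, b.beta)
        assert np.all((a.beta >= 0) & (a.beta <= 1))


def test_overlapping_explicit_dmrs_rejected(cohort_map):
    regions = (
        PlantedDMR("chr1", 1000, 3000, "hypo", -0.4),
        PlantedDMR("chr1", 2500, 4000, "hypo", -0.4),
    )
    with pytest.raises(ConfigError):
        simulate_tissue_methylomes(
            cohort_map, dmr_spec=DmrPlantSpec(regions=regions), seed=1
        )


def test_out_of_range_means_clamped_with_warning(cohort_map, called_dmrs):
    # +0.4 on an already highly methylated hypo-territory region exceeds 1
    body = next(d for d in called_dmrs if d.direction == "hypo")
    regions = (PlantedDMR(body.chrom, body.start, body.end, "hyper", +0.4),)
    with pytest.warns(UserWarning, match="clamped"):
        tissues, _ = simulate_tissue_methylomes(
            cohort_map, dmr_spec=DmrPlantSpec(regions=regions), seed=1
        )
    assert all(np.all((t.beta >= 0) & (t.beta <= 1)) for t in tissues)


# ---------------------------------------------------------- fragment length

def test_nontumor_length_mode_is_mononucleosomal():
    rng = np.random.default_rng(0)
    lengths = sample_fragment_length("nontumor", rng, size=100_000)
    counts = np.bincount(lengths)
    assert int(np.argmax(counts)) == 167


def test_tumor_fragments_are_shorter_on_average():
    rng = np.random.default_rng(1)
    t = sample_fragment_length("tumor", rng, size=100_000)
    n = sample_fragment_length("nontumor", rng, size=100_000)
    assert t.mean() < n.mean()
    assert int(np.argmax(np.bincount(t))) == TUMOR_LENGTHS.mode_bp


def test_length_sampling_is_seeded():
    a = sample_fragment_length("nontumor", np.random.default_rng(42), size=1000)
    b = sample_fragment_length("nontumor", np.random.default_rng(42), size=1000)
    assert np.array_equal(a, b)
    single = sample_fragment_length("tumor", np.random.default_rng(0))
    assert isinstance(single, int)
    assert NONTUMOR_LENGTHS.min_bp <= single <= NONTUMOR_LENGTHS.max_bp


# ------------------------------------------------------------------- plasma

def test_zero_tumor_fraction_yields_pure_nontumor(cohort_map, tissue_refs):
    s = simulate_plasma_sample(cohort_map, tissue_refs, 0.0, 2_000, seed=3)
    assert not s.truth.fragment_origins.any()
    assert s.truth.tumor_fraction == 0.0


def test_noiseless_fully_methylated_reference():
    m = make_toy_map({"chr1": list(range(100, 9900, 25))})
    refs = make_methylomes(m.n_sites, 1.0, 1.0)
    s = simulate_plasma_sample(m, refs, 1.0, 1_000, noise=0.0, seed=4)
    assert s.truth.fragment_origins.all()
    assert np.all(s.fragments.cpg_state == 1)


def test_tumor_fraction_out_of_range_rejected(cohort_map, tissue_refs):
    with pytest.raises(ValueError):
        simulate_plasma_sample(cohort_map, tissue_refs, 1.5, 100, seed=0)


def test_plasma_sample_deterministic(cohort_map, tissue_refs):
    a = simulate_plasma_sample(cohort_map, tissue_refs, 0.1, 2_000, seed=9)
    b = simulate_plasma_sample(cohort_map, tissue_refs, 0.1, 2_000, seed=9)
    assert np.array_equal(a.fragments.start, b.fragments.start)
    assert np.array_equal(a.fragments.cpg_state, b.fragments.cpg_state)


# ------------------------------------------------------------------- cohort

def test_default_discovery_cohort_counts(cohort_map, tissue_sim):
    tissues, _ = tissue_sim
    samples, records = simulate_cohort(cohort_map, tissues, seed=2)
    labels = [r.label for r in records]
    assert labels.count("malignant") == 77 and labels.count("benign") == 77
    assert len(samples) == 154
    assert all(r.birads_sub in ("4a", "4b", "4c") for r in records)
    assert all((r.stage is None) == (r.label == "benign") for r in records)
    # stage-conditional tumor-fraction means ordered I < II < III
    by_stage = {}
    for s, r in zip(samples, records):
        if r.stage in ("I", "II", "III"):
            by_stage.setdefault(r.stage, []).append(s.truth.tumor_fraction)
    means = [np.mean(by_stage[st]) for st in ("I", "II", "III")]
    assert means[0] < means[1] < means[2]


def test_null_imaging_signal_is_uninformative(cohort_map, tissue_sim):
    from sklearn.metrics import roc_auc_score

    tissues, _ = tissue_sim
    cfg = CohortConfig(n_malignant=60, n_benign=60, n_fragments=200,
                       imaging_signal=0.0, ultrasound_signal=0.0)
    _, records = simulate_cohort(cohort_map, tissues, cfg, seed=8)
    y = [r.label == "malignant" for r in records]
    auc_m = roc_auc_score(y, [r.mammography_score for r in records])
    auc_u = roc_auc_score(y, [r.ultrasound_score for r in records])
    assert 0.35 <= auc_m <= 0.65 and 0.35 <= auc_u <= 0.65


def test_undersized_cohort_rejected(cohort_map, tissue_sim):
    tissues, _ = tissue_sim
    with pytest.raises(ConfigError):
        simulate_cohort(cohort_map, tissues, CohortConfig(n_malignant=1), seed=0)
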