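import numpy as np
import pytest
from scipy import stats

from mitoclock import (
    DemographicModel,
    PMDModel,
    SampleRecord,
    SimulationError,
    SubstitutionModelSpec,
    TimeTree,
    ValidationError,
    expected_damaged_sites,
    inject_damage,
    perturb_ages,
    simulate_alignment,
    simulate_genealogy,
)
from mitoclock.io import Alignment, SampleClass, SiteAnnotation
from mitoclock.simulate import mtdna_like_annotation, PARTITION_RATES

from conftest import flat_annotation, make_panel


def two_tip_tree(total_path_years, tip_ids=("a", "b")):
    h = total_path_years / 2.0
    return TimeTree(list(tip_ids), [2, 2, -1], [-1, -1, 0], [-1, -1, 1],
                    [0.0, 0.0, h], 2)


PAIR = [SampleRecord("a", 0, 0, SampleClass.modern),
        SampleRecord("b", 0, 0, SampleClass.modern)]


# ------------------------------------------------------------------ genealogy


def test_pairwise_coalescent_mean_matches_closed_form(rng):
    """Two contemporary tips under constant Ne: E[TMRCA] = N0 * generation."""
    demo = DemographicModel(variant="constant", N0=1_000.0, growth_rate=0.0)
    n = 5_000
    tm = np.array([simulate_genealogy(PAIR, demo, rng=rng).age[2]
                   for _ in range(n)])
    expected = demo.N0 * demo.generation_time
    se = expected / np.sqrt(n)  # exponential: sd = mean
    assert abs(tm.mean() - expected) < 3 * se


def test_tmrca_never_younger_than_an_ancient_tip(rng):
    samples = [SampleRecord("m", 0, 0, SampleClass.modern),
               SampleRecord("anc", 30_000, 300, SampleClass.ancient_AMH)]
    demo = DemographicModel()
    for _ in range(200):
        t = simulate_genealogy(samples, demo, rng=rng)
        assert t.age[t.root] >= 30_000


def test_growth_compresses_coalescent_times(rng):
    n = 5_000
    demo0 = DemographicModel(variant="constant", N0=5_000.0, growth_rate=0.0)
    demo1 = DemographicModel(variant="exp_growth", N0=5_000.0, growth_rate=5e-5)
    t0 = np.mean([simulate_genealogy(PAIR, demo0, rng=rng).age[2] for _ in range(n)])
    t1 = np.mean([simulate_genealogy(PAIR, demo1, rng=rng).age[2] for _ in range(n)])
    assert t1 < t0


def test_serial_constant_model_matches_msprime():
    """Heterochronous TMRCA distribution vs an independent coalescent
    simulator (two-sample KS)."""
    import msprime

    gen = 25.0
    N0 = 4_000.0
    samples = [SampleRecord("m1", 0, 0, SampleClass.modern),
               SampleRecord("m2", 0, 0, SampleClass.modern),
               SampleRecord("a1", 15_000, 0, SampleClass.ancient_AMH),
               SampleRecord("a2", 30_000, 0, SampleClass.ancient_AMH)]
    demo = DemographicModel(variant="constant", N0=N0, growth_rate=0.0,
                            generation_time=gen)
    rng = np.random.default_rng(5)
    n = 2_000
    ours = np.array([simulate_genealogy(samples, demo, rng=rng).age.max()
                     for _ in range(n)])
    sampsets = [msprime.SampleSet(1, time=s.age_mean / gen, ploidy=1)
                for s in samples]
    theirs = np.array([
        ts.max_root_time * gen
        for ts in msprime.sim_ancestry(
            samples=sampsets, population_size=N0, ploidy=1,
            num_replicates=n, random_seed=7)
    ])
    assert stats.ks_2samp(ours, theirs).pvalue > 0.01


def test_growth_overflow_raises_simulation_error():
    samples = [SampleRecord("m", 0, 0, SampleClass.modern),
               SampleRecord("anc", 60_000, 0, SampleClass.ancient_AMH)]
    demo = DemographicModel(variant="exp_growth", N0=1e4, growth_rate=0.02)
    with pytest.raises(SimulationError, match="overflow"):
        simulate_genealogy(samples, demo, seed=1)


def test_genealogy_needs_two_samples():
    with pytest.raises(ValidationError):
        simulate_genealogy(PAIR[:1], DemographicModel(), seed=0)


# ------------------------------------------------------------------ sequences

JC = SubstitutionModelSpec(model="JC")


def test_zero_branch_lengths_give_identical_sequences(rng):
    t = two_tip_tree(0.0)
    ann = flat_annotation(500)
    aln = simulate_alignment(t, ann, {"all": (JC, 1e-8)}, rng=rng)
    assert aln.sequence(0) == aln.sequence(1)


def test_jc_pairwise_difference_matches_closed_form(rng):
    """Total path mu*t = 0.1: P(diff) = (3/4)(1 - exp(-0.4/3))."""
    mu, L = 1e-8, 50_000
    t = two_tip_tree(0.1 / mu)
    aln = simulate_alignment(t, flat_annotation(L), {"all": (JC, mu)}, rng=rng)
    p_hat = np.mean(aln.codes[0] != aln.codes[1])
    p_exp = 0.75 * (1.0 - np.exp(-4.0 * 0.1 / 3.0))
    se = np.sqrt(p_exp * (1 - p_exp) / L)
    assert abs(p_hat - p_exp) < 3 * se


def test_transition_transversion_ratio_tracks_kappa(rng):
    """Observed ts/tv between two tips matches the transition-matrix
    expectation for an HKY model with strong transition bias."""
    from mitoclock.substitution import transition_matrix

    kappa, mu, L = 20.0, 1e-8, 60_000
    pi = (0.3, 0.3, 0.2, 0.2)
    spec = SubstitutionModelSpec(model="HKY", kappa=kappa, pi=pi)
    d = 0.06
    t = two_tip_tree(d / mu)
    aln = simulate_alignment(t, flat_annotation(L), {"all": (spec, mu)}, rng=rng)
    a, b = aln.codes[0], aln.codes[1]
    ts_pairs = {(0, 2), (2, 0), (1, 3), (3, 1)}
    diff = a != b
    ts = sum(1 for x, y in zip(a[diff], b[diff]) if (int(x), int(y)) in ts_pairs)
    tv = int(diff.sum()) - ts
    # expectation from the model's own transition probabilities (independent path)
    P = transition_matrix(spec, d)
    e_ts = sum(pi[i] * P[i, j] for i, j in ((0, 2), (1, 3), (2, 0), (3, 1)))
    e_tv = sum(pi[i] * P[i, j] for i in range(4) for j in range(4)
               if i != j and (i, j) not in ts_pairs)
    assert ts / tv == pytest.approx(e_ts / e_tv, rel=0.2)


def test_pc3_diversity_exceeds_pc12_diversity(rng):
    """Third codon positions evolve ~4x faster than first+second."""
    ann = mtdna_like_annotation(3_000)
    spec = SubstitutionModelSpec(model="HKY", kappa=22.0, pi=(0.31, 0.31, 0.13, 0.25))
    parts = {"PC1+PC2": (spec, PARTITION_RATES["PC1+PC2"]),
             "PC3": (spec, PARTITION_RATES["PC3"])}
    panel = make_panel(8, 2)
    demo = DemographicModel()
    wins = 0
    n_rep = 40
    pc12 = ann.sites_of(("PC1", "PC2"))
    pc3 = ann.sites_of("PC3")
    for _ in range(n_rep):
        tree = simulate_genealogy(panel, demo, rng=rng)
        aln = simulate_alignment(tree, ann, parts, rng=rng)
        div12 = np.mean([np.mean(aln.codes[i, pc12] != aln.codes[j, pc12])
                         for i in range(5) for j in range(i + 1, 5)])
        div3 = np.mean([np.mean(aln.codes[i, pc3] != aln.codes[j, pc3])
                        for i in range(5) for j in range(i + 1, 5)])
        wins += div3 > div12
    assert wins >= n_rep - 1


def test_empty_partition_warns_and_skips(rng, small_tree):
    ann = flat_annotation(100)
    with pytest.warns(UserWarning, match="zero sites"):
        simulate_alignment(small_tree, ann,
                           {"all": (JC, 1e-8), "HVS1": (JC, 1e-8)}, rng=rng)


# --------------------------------------------------------------------- damage


def test_zero_delta_is_identity(rng, small_panel, small_tree):
    aln = simulate_alignment(small_tree, flat_annotation(300), {"all": (JC, 1e-8)},
                             rng=rng)
    assert inject_damage(aln, small_panel, PMDModel(0.0), rng=rng) == aln


def test_damage_only_creates_ct_and_ga_on_ancient_rows(rng, small_panel, small_tree):
    aln = simulate_alignment(small_tree, flat_annotation(2_000), {"all": (JC, 1e-8)},
                             rng=rng)
    damaged = inject_damage(aln, small_panel, PMDModel(5e-6), rng=rng)
    ancient_ids = {s.sample_id for s in small_panel if s.is_ancient}
    changed_rows = 0
    for i, sid in enumerate(aln.ids):
        diff = np.flatnonzero(aln.codes[i] != damaged.codes[i])
        if diff.size:
            changed_rows += 1
            assert sid in ancient_ids
            for col in diff:
                before, after = aln.codes[i, col], damaged.codes[i, col]
                assert (before, after) in {(1, 3), (2, 0)}  # C->T or G->A
    assert changed_rows > 0


def test_tianyuan_damage_expectation(rng):
    """delta = 1.03e-9 over 39,464 years and 16,569 eligible sites gives
    an expectation of 0.67 deaminated positions."""
    pmd = PMDModel(1.03e-9)
    exp = expected_damaged_sites(pmd, 39_464, 16_569)
    assert round(exp, 2) == 0.67
    # simulation agrees: all-C sequence, count flips
    L = 16_569
    sample = [SampleRecord("t", 39_464, 639, SampleClass.ancient_AMH)]
    aln = Alignment(["t"], np.full((1, L), 1, dtype=np.uint8))
    n = 3_000
    flips = np.array([
        int((inject_damage(aln, sample, pmd, rng=rng).codes != aln.codes).sum())
        for _ in range(n)
    ])
    se = np.sqrt(exp / n)  # Poisson-like
    assert abs(flips.mean() - exp) < 3 * se


# ----------------------------------------------------------------- age error


def test_perturb_ages_identity_when_sd_zero(rng):
    samples = [SampleRecord("a", 10_000, 0, SampleClass.ancient_AMH)]
    assert perturb_ages(samples, rng=rng) == samples


def test_perturb_ages_moments_and_truncation(rng):
    s = SampleRecord("a", 20_000, 1_000, SampleClass.ancient_AMH)
    draws = np.array([perturb_ages([s], rng=rng)[0].age_mean
                      for _ in range(10_000)])
    assert abs(draws.mean() - 20_000) < 3 * 1_000 / np.sqrt(10_000)
    assert abs(draws.std() - 1_000) / 1_000 < 0.05
    # heavy truncation: ages stay non-negative
    s2 = SampleRecord("b", 500, 1_000, SampleClass.ancient_AMH)
    draws2 = np.array([perturb_ages([s2], rng=rng)[0].age_mean
                       for _ in range(2_000)])
    assert np.all(draws2 >= 0)


def test_modern_tips_unchanged(rng):
    samples = make_panel(3, 2)
    out = perturb_ages(samples, rng=rng)
    for before, after in zip(samples, out):
        if not before.is_ancient:
            assert before == after


def test_paper_like_panel_fixture_composition():
    """The repository's main fixture: ~300 contemporary + 25 ancient tips
    spanning 2.5-40 ka + 5 archaic tips to 65 ka, with per-partition rates
    and an mtDNA-like annotation."""
    from mitoclock.simulate import paper_like_panel, simulate_panel

    samples, tree, aln, ann = simulate_panel(
        samples=paper_like_panel(2024), n_sites=2_000, seed=2024)
    classes = {}
    for s in samples:
        classes.setdefault(s.sample_class.value, []).append(s)
    assert len(classes["modern"]) == 300
    assert len(classes["ancient_AMH"]) == 25
    assert len(classes["archaic"]) == 5
    anc_ages = sorted(s.age_mean for s in classes["ancient_AMH"])
    assert 2_000 < anc_ages[0] < 5_000 and 35_000 < anc_ages[-1] < 42_000
    assert max(s.age_mean for s in classes["archaic"]) == pytest.approx(64_500)
    assert all(s.age_sd > 0 for s in classes["ancient_AMH"])
    assert aln.n_sequences == 330 and aln.n_sites == 2_000
    assert tree.n_tips == 330
    assert set(np.unique(ann.labels)) <= {"HVS1", "HVS2", "PC1", "PC2",
                                          "PC3", "tRNA", "rRNA", "other"}
    # enough polymorphism to be analysis-ready
    var = int((aln.codes != aln.codes[0]).any(axis=0).sum())
    assert var > 50
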