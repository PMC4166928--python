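import dendropy
import numpy as np
import pytest

from mitoclock import DemographicModel, MCMCSettings, StructureError, ValidationError
from mitoclock.compare import (
    clade_tmrca,
    date_randomization_test,
    hpd_overlap,
    penny_hendy_distance,
    permute_ancient_ages,
    point_vs_interval_tip_comparison,
    rate_age_correlation,
    root_to_tip_regression,
    tmrca_cross_comparison,
)
from mitoclock.diagnostics import PosteriorSummary
from mitoclock.mcmc import MCMCResult
from mitoclock.simulate import simulate_genealogy

from conftest import make_panel
from helpers import brute_force_bipartitions
from test_tree import balanced_tree


# ------------------------------------------------------------- penny-hendy


def random_tree(seed, n=12):
    panel = make_panel(n, 0)
    return simulate_genealogy(panel, DemographicModel(), seed=seed)


def test_identical_trees_have_distance_zero():
    t = random_tree(1)
    assert penny_hendy_distance(t, t) == 0


def test_conflicting_quartets_have_distance_two():
    from mitoclock import TimeTree

    t1 = balanced_tree()  # ((a,b),(c,d))
    t2 = TimeTree(["a", "c", "b", "d"], [4, 4, 5, 5, 6, 6, -1],
                  [-1, -1, -1, -1, 0, 2, 4], [-1, -1, -1, -1, 1, 3, 5],
                  [0, 0, 0, 0, 10, 20, 50], 6)  # ((a,c),(b,d))
    assert penny_hendy_distance(t1, t2) == 2


def test_distance_equals_brute_force_bipartition_count():
    for seed in range(25):
        a, b = random_tree(2 * seed), random_tree(2 * seed + 1)
        expected = len(brute_force_bipartitions(a) ^ brute_force_bipartitions(b))
        d = penny_hendy_distance(a, b)
        assert d == expected
        assert d % 2 == 0


def test_distance_is_a_metric_on_random_triples():
    trees = [random_tree(s) for s in range(9)]
    for i in range(0, 9, 3):
        a, b, c = trees[i], trees[i + 1], trees[i + 2]
        assert penny_hendy_distance(a, a) == 0
        assert penny_hendy_distance(a, b) == penny_hendy_distance(b, a)
        assert (penny_hendy_distance(a, c)
                <= penny_hendy_distance(a, b) + penny_hendy_distance(b, c))


def test_pruning_to_shared_tips_before_comparison():
    a = random_tree(3, n=10)
    b = random_tree(4, n=10)
    keep = a.tip_ids[:6]
    d = penny_hendy_distance(a, b, prune_to=keep)
    assert d == penny_hendy_distance(a.prune_to(keep), b.prune_to(keep))


def test_tip_set_mismatch_raises():
    a = random_tree(5, n=6)
    b = random_tree(6, n=8)
    with pytest.raises(StructureError):
        penny_hendy_distance(a, b)


def test_hpd_overlap_is_interval_intersection():
    assert hpd_overlap((0, 2), (1, 3))
    assert hpd_overlap((0, 2), (2, 3))  # touching counts
    assert not hpd_overlap((0, 1), (2, 3))


# --------------------------------------------------- root-to-tip regression


def test_perfect_clock_recovers_rate_exactly():
    mu = 1e-8
    ns = dendropy.TaxonNamespace()
    ages = {"a": 0.0, "b": 10_000.0, "c": 30_000.0}
    # distances from root chosen as mu * (T - age): a perfect clock from
    # a root 50 ky deep
    nwk = "(a:{:.12f},(b:{:.12f},c:{:.12f}):{:.12f});".format(
        mu * 50_000, mu * 20_000, mu * 0.0, mu * 20_000)
    tree = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=ns)
    samples = make_panel(0, 0)
    from mitoclock.io import SampleClass, SampleRecord

    samples = [SampleRecord("a", 0, 0, SampleClass.modern),
               SampleRecord("b", 10_000, 100, SampleClass.ancient_AMH),
               SampleRecord("c", 30_000, 300, SampleClass.ancient_AMH)]
    fit = root_to_tip_regression(tree, samples)
    assert fit["slope"] == pytest.approx(mu, rel=1e-9)
    assert fit["r"] == pytest.approx(1.0, abs=1e-9)


def test_isochronous_tips_raise():
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree.get(data="(a:1,(b:1,c:1):1);", schema="newick",
                             taxon_namespace=ns)
    from mitoclock.io import SampleClass, SampleRecord

    samples = [SampleRecord(s, 0, 0, SampleClass.modern) for s in "abc"]
    with pytest.raises(ValidationError, match="temporal"):
        root_to_tip_regression(tree, samples)


# -------------------------------------------------------------- clade ages


def test_clade_tmrca_on_fixed_trees():
    trees = [balanced_tree() for _ in range(25)]
    out = clade_tmrca(trees, ["a", "b"])
    assert out["mean"] == 10
    assert out["hpd"] == (10, 10)
    root = clade_tmrca(trees, ["a", "b", "c", "d"])
    assert root["mean"] == 50
    single = clade_tmrca(trees, ["c"])
    assert single["mean"] == 0
    with pytest.raises(ValidationError):
        clade_tmrca(trees, [])


def test_tmrca_cross_comparison_identity_gives_r2_one():
    trees = [random_tree(7) for _ in range(5)]
    out = tmrca_cross_comparison(trees, trees)
    assert out["r_squared"] == pytest.approx(1.0, abs=1e-12)
    assert out["slope"] == pytest.approx(1.0, abs=1e-12)


def test_tmrca_cross_comparison_rejects_conflicting_topologies():
    a = [random_tree(8)]
    b = [random_tree(9)]
    with pytest.raises(StructureError):
        tmrca_cross_comparison(a, b)


# -------------------------------------------------- sweep-level statistics


def test_rate_age_correlation_constructed_line():
    ages = np.array([5_000.0, 15_000.0, 30_000.0, 45_000.0])
    rates = 3e-8 - 1e-13 * ages
    out = rate_age_correlation(ages, rates)
    assert out["r"] == pytest.approx(-1.0, abs=1e-12)


def test_rate_age_correlation_degenerate_and_small_inputs():
    assert rate_age_correlation([1e3, 2e3, 3e3], [1e-8] * 3)["degenerate"]
    with pytest.raises(ValidationError):
        rate_age_correlation([1e3, 1e3, 1e3], [1e-8, 2e-8, 3e-8])


def _fake_result(samples: dict) -> MCMCResult:
    return MCMCResult(PosteriorSummary({k: [np.asarray(v)] for k, v in samples.items()}),
                      {}, [], [], MCMCSettings(), [])


def test_point_vs_interval_identical_inputs(rng):
    x = rng.normal(1.0, 0.1, size=500)
    a = _fake_result({"rate": x, "root_age": x * 2})
    b = _fake_result({"rate": x.copy(), "root_age": x * 2})
    out = point_vs_interval_tip_comparison(a, b)
    assert out["wilcoxon_p"] == 1.0
    assert all(abs(v) < 1e-9 for v in out["hpd_width_change_pct"].values())


def test_point_vs_interval_detects_widened_hpd(rng):
    x = np.sort(rng.normal(1.0, 0.1, size=2_000))
    widened = x.mean() + 1.05 * (x - x.mean())
    a = _fake_result({"rate": x})
    b = _fake_result({"rate": widened})
    out = point_vs_interval_tip_comparison(a, b, parameters=["rate"])
    assert out["hpd_width_change_pct"]["rate"] == pytest.approx(5.0, abs=0.3)


def test_point_vs_interval_unmatched_parameters(rng):
    a = _fake_result({"rate": rng.normal(size=100)})
    b = _fake_result({"other": rng.normal(size=100)})
    with pytest.raises(ValidationError):
        point_vs_interval_tip_comparison(a, b, parameters=["rate"])


# ------------------------------------------------------- date randomization


def test_permutation_preserves_age_multiset(rng):
    panel = make_panel(5, 6)
    shuffled = permute_ancient_ages(panel, rng)
    assert sorted(s.age_mean for s in shuffled) == sorted(
        s.age_mean for s in panel)
    for s in shuffled:
        if not s.is_ancient:
            assert s.age_mean == 0
    # ids keep their class labels
    assert [s.sample_class for s in shuffled] == [s.sample_class for s in panel]


def test_zero_replicates_rejected():
    panel = make_panel(4, 3)
    from mitoclock import CalibrationSpec

    cal = CalibrationSpec(tip_priors={"a00": 2_500.0})
    with pytest.raises(ValidationError):
        date_randomization_test(None, None, panel, cal, MCMCSettings(), n_reps=0)


# ------------------------------------------------------ scenario orchestration


def _tiny_dataset():
    from mitoclock.simulate import simulate_alignment
    from mitoclock.substitution import SubstitutionModelSpec
    from conftest import flat_annotation

    hky = SubstitutionModelSpec(model="HKY", kappa=22.0,
                                pi=(0.309, 0.313, 0.131, 0.247))
    panel = make_panel(6, 5)
    demo = DemographicModel()
    rng = np.random.default_rng(12)
    tree = simulate_genealogy(panel, demo, rng=rng)
    ann = flat_annotation(800)
    aln = simulate_alignment(tree, ann, {"all": (hky, 2.143e-8)}, rng=rng)
    return panel, demo, tree, ann, aln, hky


def test_run_scenarios_is_deterministic_per_label():
    from mitoclock import CalibrationSpec, NodeCalibration
    from mitoclock.compare import run_scenarios
    from mitoclock.mcmc import default_partitions

    panel, demo, tree, ann, aln, hky = _tiny_dataset()
    tips_all = CalibrationSpec(
        tip_priors={s.sample_id: s.age_mean for s in panel if s.is_ancient},
        node_age_bounds=(0.0, 50e6), bound_all_internal_nodes=False)
    modern_ids = [s.sample_id for s in panel if not s.is_ancient]
    nodes = CalibrationSpec(
        node_priors=[NodeCalibration(frozenset(modern_ids),
                                     tree.tmrca(modern_ids))],
        node_age_bounds=(0.0, 50e6), bound_all_internal_nodes=False)
    settings = MCMCSettings(steps=1_500, burn_in=300, thin=10, seed=21,
                            store_trees=False)
    kw = dict(partitions=default_partitions(2e-8, spec=hky),
              start_tree=tree, demography=demo)
    a = run_scenarios(aln, ann, panel, {"tips_all": tips_all, "nodes": nodes},
                      settings, **kw)
    b = run_scenarios(aln, ann, panel, {"tips_all": tips_all, "nodes": nodes},
                      settings, **kw)
    assert [r.label for r in a] == ["tips_all", "nodes"]
    for ra, rb in zip(a, b):
        assert ra.rate_mean == rb.rate_mean
        assert ra.rate_hpd == rb.rate_hpd


def test_individual_calibration_sweep_reports_overlaps():
    from mitoclock import CalibrationSpec
    from mitoclock.compare import individual_calibration_sweep
    from mitoclock.mcmc import default_partitions

    panel, demo, tree, ann, aln, hky = _tiny_dataset()
    ancients = [s for s in panel if s.is_ancient][:3]
    cals = []
    for s in ancients:
        spec = CalibrationSpec(tip_priors={s.sample_id: s.age_mean},
                               node_age_bounds=(0.0, 50e6),
                               bound_all_internal_nodes=False)
        cals.append((s.sample_id, "tip", s.age_mean, spec))
    settings = MCMCSettings(steps=1_500, burn_in=300, thin=10, seed=5,
                            store_trees=False)
    rep = individual_calibration_sweep(
        aln, ann, panel, cals, settings,
        partitions=default_partitions(2e-8, spec=hky),
        start_tree=tree, demography=demo)
    assert rep.overlap_matrix.shape == (3, 3)
    assert np.all(np.diag(rep.overlap_matrix))
    assert rep.variance_ratio is None  # tips only, no nodes
    assert 0.0 <= rep.overlap_fraction("tip") <= 1.0
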