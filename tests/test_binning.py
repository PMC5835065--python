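"""Clustering, composition refinement and paired-end link recruitment."""

import numpy as np
import pytest

from nitrosyn.binning import (
    BinAssignment,
    cluster_bins,
    recruit_by_links,
    refine_by_composition,
)
from nitrosyn.coverage import prepare_coverage
from nitrosyn.evaluate import evaluate_bins
from nitrosyn.features import ContigFeatures, contig_features
from nitrosyn.mds import Embedding, classical_mds
from nitrosyn.synthcom import CommunityConfig, LinkGraph, generate_community


def _embedding(points: np.ndarray) -> Embedding:
    centred = points - points.mean(axis=0)
    return Embedding(coords=centred, eigenvalues=np.ones(points.shape[1]))


# --- clustering ------------------------------------------------------------


def test_two_separated_clouds_select_k2_with_perfect_recovery():
    rng = np.random.default_rng(0)
    pts = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(20, 1, (40, 2))])
    ids = [f"c{i:03d}" for i in range(80)]
    bins = cluster_bins(_embedding(pts), ids, 2, 5, seed=1)
    assert bins.k == 2
    truth = {ids[i]: ("A" if i < 40 else "B") for i in range(80)}
    assert evaluate_bins(bins, truth)["ari"] == pytest.approx(1.0)


def test_identical_points_return_single_degenerate_bin():
    pts = np.zeros((10, 2))
    bins = cluster_bins(_embedding(pts), [f"c{i}" for i in range(10)], 2, 4, seed=0)
    assert bins.degenerate
    assert bins.labels() == {0}
    assert not bins.unbinned()


def test_clustering_is_deterministic_for_fixed_seed():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(60, 3))
    ids = [f"c{i:03d}" for i in range(60)]
    a = cluster_bins(_embedding(pts), ids, 2, 6, seed=9)
    b = cluster_bins(_embedding(pts), ids, 2, 6, seed=9)
    assert a.assignment == b.assignment and a.k == b.k


def test_cluster_bins_validates_k_range():
    pts = np.arange(10.0).reshape(5, 2)
    with pytest.raises(ValueError):
        cluster_bins(_embedding(pts), [f"c{i}" for i in range(5)], 2, 5, seed=0)


def test_default_community_clustering_resolves_genomes(default_community):
    cfg, contigs, cov, _ = default_community
    emb = classical_mds(prepare_coverage(cov), min(3, len(cov.samples)))
    bins = cluster_bins(emb, cov.contig_ids, 2, 16, seed=4)
    assert evaluate_bins(bins, contigs.truth())["ari"] >= 0.95


# --- composition refinement ------------------------------------------------


def test_alien_contig_is_unbinned_by_composition():
    # 20 contigs from one generator plus 1 from a generator 0.15 GC away
    cfg = CommunityConfig(n_genomes=2, genome_length_bp=60_000, contig_mean_bp=3_000,
                          gc_targets=[0.42, 0.57], seed=5)
    contigs, _, _ = generate_community(cfg)
    own = [r for r in contigs.records if r.genome == "genome01"][:20]
    alien = next(r for r in contigs.records if r.genome == "genome02")
    members = own + [alien]
    bins = BinAssignment(assignment={r.contig_id: 0 for r in members},
                         provenance={r.contig_id: "cluster" for r in members})
    feats = {r.contig_id: contig_features(r.sequence) for r in members}
    refined = refine_by_composition(bins, feats, z_max=3.0)
    assert refined.assignment[alien.contig_id] is None
    assert refined.provenance[alien.contig_id] == "composition_removed"


def test_homogeneous_bin_keeps_all_members():
    # identical TNF (MAD 0 -> criterion skipped) and bounded-uniform GC
    # jitter whose max robust z is ~1.35: no outliers by construction
    rng = np.random.default_rng(1)
    tnf = np.full(136, 1.0 / 136)
    feats = {
        f"c{i}": ContigFeatures(gc=0.5 + float(rng.uniform(-0.01, 0.01)), tnf=tnf)
        for i in range(30)
    }
    bins = BinAssignment(assignment={c: 0 for c in feats},
                         provenance={c: "cluster" for c in feats})
    refined = refine_by_composition(bins, feats, z_max=3.0)
    assert refined.assignment == bins.assignment


def test_tiny_bins_are_never_pruned():
    tnf_a = np.zeros(136); tnf_a[0] = 1.0
    tnf_b = np.zeros(136); tnf_b[-1] = 1.0
    feats = {"x": ContigFeatures(0.2, tnf_a), "y": ContigFeatures(0.8, tnf_b)}
    bins = BinAssignment(assignment={"x": 0, "y": 0},
                         provenance={"x": "cluster", "y": "cluster"})
    assert refine_by_composition(bins, feats).assignment == bins.assignment


def test_refinement_is_conservative(default_community):
    # never adds contigs to a bin, never renames bins
    cfg, contigs, cov, _ = default_community
    emb = classical_mds(prepare_coverage(cov), 3)
    bins = cluster_bins(emb, cov.contig_ids, 2, 16, seed=4)
    feats = {r.contig_id: contig_features(r.sequence) for r in contigs.records}
    refined = refine_by_composition(bins, feats, z_max=3.0)
    assert refined.labels() <= bins.labels()
    for c in bins.assignment:
        assert refined.assignment[c] in (bins.assignment[c], None)


# --- link recruitment ------------------------------------------------------


def _two_bin_state():
    assignment = {f"a{i}": 0 for i in range(5)} | {f"b{i}": 1 for i in range(5)}
    assignment["u"] = None
    return BinAssignment(assignment=assignment,
                         provenance={c: "cluster" for c in assignment})


def test_unbinned_contig_with_clear_majority_is_recruited():
    bins = _two_bin_state()
    links = LinkGraph(edges=[("u", "a0", 5), ("u", "b0", 1)])
    out = recruit_by_links(bins, links)
    assert out.assignment["u"] == 0
    assert out.provenance["u"] == "link_recruited"


def test_tied_links_leave_contig_unbinned():
    bins = _two_bin_state()
    links = LinkGraph(edges=[("u", "a0", 1), ("u", "b0", 1)])
    out = recruit_by_links(bins, links)
    assert out.assignment["u"] is None  # 1/2 does not strictly exceed 0.5


def test_misassigned_contig_is_moved_by_link_majority():
    bins = _two_bin_state()
    links = LinkGraph(edges=[("a0", "b0", 4), ("a0", "b1", 4), ("a0", "a1", 1)])
    out = recruit_by_links(bins, links)
    assert out.assignment["a0"] == 1  # 8/9 >= 0.7
    assert out.provenance["a0"] == "link_reassigned"


def test_min_links_floor_blocks_recruitment():
    bins = _two_bin_state()
    links = LinkGraph(edges=[("u", "a0", 1)])
    out = recruit_by_links(bins, links, min_links=2)
    assert out.assignment["u"] is None


def test_decisions_use_frozen_pre_pass_state():
    # u1 links only to u2; u2 links mostly to bin 0: u1 must not chain-recruit
    assignment = {f"a{i}": 0 for i in range(3)} | {"u1": None, "u2": None}
    bins = BinAssignment(assignment=assignment,
                         provenance={c: "cluster" for c in assignment})
    links = LinkGraph(edges=[("u1", "u2", 2), ("u2", "a0", 6)])
    out = recruit_by_links(bins, links)
    assert out.assignment["u2"] == 0
    assert out.assignment["u1"] is None


def test_recruitment_never_hurts_without_spurious_links():
    # with no spurious links, a recruitment pass must not decrease ARI
    for seed in range(20):
        cfg = CommunityConfig(
            n_genomes=4, genome_length_bp=50_000, contig_mean_bp=2_500,
            spurious_link_rate=0.0, coverage_noise_cv=0.3,
            abundance_trajectories=[[20, 60, 30], [50, 20, 10], [10, 30, 60], [40, 40, 40]],
            gc_targets=[0.4, 0.5, 0.6, 0.45], seed=seed,
        )
        contigs, cov, links = generate_community(cfg)
        emb = classical_mds(prepare_coverage(cov), 3)
        bins = cluster_bins(emb, cov.contig_ids, 2, 8, seed=seed)
        truth = contigs.truth()
        before = evaluate_bins(bins, truth)["ari"]
        after = evaluate_bins(recruit_by_links(bins, links), truth)["ari"]
        assert after >= before - 1e-12, f"seed {seed}: ARI fell {before} -> {after}"


def test_recruit_parameter_validation():
    bins = _two_bin_state()
    links = LinkGraph(edges=[])
    with pytest.raises(ValueError):
        recruit_by_links(bins, links, add_frac=0.4)
    with pytest.raises(ValueError):
        recruit_by_links(bins, links, add_frac=0.8, reassign_frac=0.7)
    with pytest.raises(ValueError):
        recruit_by_links(bins, links, min_links=0)
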