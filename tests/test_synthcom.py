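"""Synthetic community generator: determinism, labels, noise law, links, markers."""

import itertools

import numpy as np
import pytest
from pydantic import ValidationError

from nitrosyn.features import contig_features, gc_content
from nitrosyn.synthcom import (
    CommunityConfig,
    ContigRecord,
    ContigSet,
    LinkGraph,
    generate_community,
    plant_markers,
)


def test_fixed_seed_reproduces_byte_identical_outputs():
    cfg = CommunityConfig(n_genomes=8, n_timepoints=3, seed=7,
                          genome_length_bp=40_000)
    a = generate_community(cfg)
    b = generate_community(cfg)
    assert [(r.contig_id, r.sequence, r.genome) for r in a[0].records] == \
           [(r.contig_id, r.sequence, r.genome) for r in b[0].records]
    assert a[0].markers == b[0].markers
    np.testing.assert_array_equal(a[1].values, b[1].values)
    assert a[2].edges == b[2].edges


def test_every_contig_carries_one_of_k_truth_labels(default_community):
    cfg, contigs, cov, links = default_community
    labels = {r.genome for r in contigs.records}
    assert len(labels) == cfg.n_genomes
    assert all(r.genome is not None for r in contigs.records)
    assert all(len(r.sequence) >= cfg.contig_min_bp for r in contigs.records)


def test_label_completeness_across_outputs(default_community):
    _, contigs, cov, links = default_community
    ids = set(contigs.contig_ids)
    assert set(cov.contig_ids) == ids
    for a, b, _ in links.edges:
        assert a in ids and b in ids


def test_zero_spurious_rate_gives_only_intra_genome_links():
    cfg = CommunityConfig(n_genomes=4, genome_length_bp=40_000,
                          spurious_link_rate=0.0, seed=3,
                          gc_targets=[0.4, 0.5, 0.55, 0.6])
    contigs, _, links = generate_community(cfg)
    truth = contigs.truth()
    assert links.edges, "expected some links"
    assert all(truth[a] == truth[b] for a, b, _ in links.edges)


def test_coverage_follows_abundance_trajectory_in_the_mean():
    # genome with trajectory (1, 2, 3) and CV 0.1: with >=200 contigs the
    # per-timepoint means must sit within 5% of the 1:2:3 ratios
    cfg = CommunityConfig(
        n_genomes=2, genome_length_bp=150_000, contig_min_bp=500,
        contig_mean_bp=700, n_timepoints=3,
        abundance_trajectories=[[1, 2, 3], [5, 5, 5]],
        coverage_noise_cv=0.1, gc_targets=[0.45, 0.55], seed=3,
    )
    contigs, cov, _ = generate_community(cfg)
    rows = [i for i, r in enumerate(contigs.records) if r.genome == "genome01"]
    assert len(rows) >= 200
    mean = cov.values[rows].mean(axis=0)
    np.testing.assert_allclose(mean / mean[0], [1.0, 2.0, 3.0], rtol=0.05)


def test_coverage_positive_with_noise(default_community):
    _, _, cov, _ = default_community
    assert (cov.values > 0).all()


def test_gc_targets_are_hit(default_community):
    cfg, contigs, _, _ = default_community
    targets = dict(zip(sorted(contigs.by_genome()), cfg.resolved_gc()))
    for genome, ids in contigs.by_genome().items():
        recs = {r.contig_id: r for r in contigs.records}
        seq = "".join(recs[c].sequence for c in ids)
        assert abs(gc_content(seq) - targets[genome]) < 0.02


def test_composition_signatures_separate_genomes(default_community):
    # genomes with GC differing by >=0.08: between-genome TNF distance must
    # exceed within-genome distance on average
    cfg, contigs, _, _ = default_community
    recs = {r.contig_id: r for r in contigs.records}
    gcs = dict(zip(sorted(contigs.by_genome()), cfg.resolved_gc()))
    rng = np.random.default_rng(0)
    sample = rng.choice(contigs.contig_ids, size=120, replace=False)
    feats = {c: contig_features(recs[c].sequence) for c in sample}
    within, between = [], []
    for a, b in itertools.combinations(sample, 2):
        d = float(np.linalg.norm(feats[a].tnf - feats[b].tnf))
        ga, gb = recs[a].genome, recs[b].genome
        if ga == gb:
            within.append(d)
        elif abs(gcs[ga] - gcs[gb]) >= 0.08:
            between.append(d)
    assert np.mean(between) > np.mean(within)


def test_plant_markers_places_each_pair_exactly_once(default_community):
    _, contigs, _, _ = default_community
    planted = plant_markers(contigs, n_markers=100, seed=5)
    assert len(planted.markers) == 8 * 100
    truth = planted.truth()
    seen = {(truth[c], m) for c, m in planted.markers}
    assert len(seen) == 8 * 100  # each (genome, marker) pair exactly once
    # determinism
    again = plant_markers(contigs, n_markers=100, seed=5)
    assert planted.markers == again.markers


def test_plant_single_marker_marks_every_genome(default_community):
    _, contigs, _, _ = default_community
    planted = plant_markers(contigs, n_markers=1, seed=0)
    truth = planted.truth()
    assert sorted({truth[c] for c, _ in planted.markers}) == sorted(contigs.by_genome())
    assert len(planted.markers) == 8


def test_config_validation():
    with pytest.raises(ValidationError):
        CommunityConfig(n_genomes=1)
    with pytest.raises(ValidationError):
        CommunityConfig(n_genomes=2, n_timepoints=2,
                        abundance_trajectories=[[1.0, 0.0], [1.0, 1.0]],
                        gc_targets=[0.4, 0.6])
    with pytest.raises(ValidationError):
        CommunityConfig(spurious_link_rate=1.5)
    with pytest.raises(ValidationError):
        CommunityConfig(genome_length_bp=-5)


def test_link_graph_rejects_self_edges_and_bad_counts():
    with pytest.raises(ValueError):
        LinkGraph(edges=[("a", "a", 2)])
    with pytest.raises(ValueError):
        LinkGraph(edges=[("a", "b", 0)])


def test_contig_set_rejects_duplicate_ids():
    rec = ContigRecord("c1", "ACGT", "g")
    with pytest.raises(ValueError):
        ContigSet(records=[rec, rec])
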