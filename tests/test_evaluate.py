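"""Partition agreement (ARI) and marker-based bin quality."""

from itertools import combinations

import numpy as np
import pytest

from nitrosyn.binning import BinAssignment
from nitrosyn.evaluate import evaluate_bins, marker_quality


def brute_force_ari(labels_a, labels_b):
    """Independent ARI oracle: direct evaluation of the contingency formula."""
    pairs = list(combinations(range(len(labels_a)), 2))
    n_pairs = len(pairs)
    sum_ij = sum(
        1 for i, j in pairs if labels_a[i] == labels_a[j] and labels_b[i] == labels_b[j]
    )
    sum_a = sum(1 for i, j in pairs if labels_a[i] == labels_a[j])
    sum_b = sum(1 for i, j in pairs if labels_b[i] == labels_b[j])
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


def _bins(mapping):
    return BinAssignment(assignment=dict(mapping),
                         provenance={c: "cluster" for c in mapping})


def test_perfect_recovery_scores_ari_one():
    truth = {f"c{i}": f"g{i % 2}" for i in range(8)}
    bins = _bins({c: int(g[1]) for c, g in truth.items()})
    assert evaluate_bins(bins, truth)["ari"] == pytest.approx(1.0)


def test_single_bin_against_two_genomes_is_chance_level():
    truth = {f"c{i}": ("g1" if i < 4 else "g2") for i in range(8)}
    bins = _bins({c: 0 for c in truth})
    assert evaluate_bins(bins, truth)["ari"] == pytest.approx(0.0)


def test_ari_matches_hand_contingency_value():
    # contingency [[2,1],[1,2]] over 6 items: ARI = -1/9 by direct formula
    truth = {"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g2", "f": "g2"}
    pred = {"a": 0, "b": 0, "c": 1, "d": 0, "e": 1, "f": 1}
    report = evaluate_bins(_bins(pred), truth)
    oracle = brute_force_ari(list(truth.values()), [pred[c] for c in truth])
    assert oracle == pytest.approx(-1 / 9)
    assert report["ari"] == pytest.approx(oracle)


def test_ari_symmetry_and_label_permutation_invariance():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 3, 30)
    b = rng.integers(0, 4, 30)
    ids = [f"c{i}" for i in range(30)]
    ari_ab = evaluate_bins(_bins(dict(zip(ids, a))), dict(zip(ids, map(str, b))))["ari"]
    ari_ba = evaluate_bins(_bins(dict(zip(ids, b))), dict(zip(ids, map(str, a))))["ari"]
    assert ari_ab == pytest.approx(ari_ba)
    assert ari_ab == pytest.approx(brute_force_ari(list(a), list(b)))
    # permute predicted labels: invariant
    perm = {0: 2, 1: 0, 2: 1}
    ari_perm = evaluate_bins(_bins(dict(zip(ids, (perm[x] for x in a)))),
                             dict(zip(ids, map(str, b))))["ari"]
    assert ari_perm == pytest.approx(ari_ab)


def test_unbinned_contigs_excluded_from_ari_but_counted_in_fraction():
    truth = {f"c{i}": "g1" for i in range(4)} | {f"d{i}": "g2" for i in range(4)}
    assignment = {c: (0 if c.startswith("c") else 1) for c in truth}
    assignment["c0"] = None
    report = evaluate_bins(_bins(assignment), truth)
    assert report["ari"] == pytest.approx(1.0)
    assert report["unbinned_fraction"] == pytest.approx(1 / 8)


def test_per_bin_precision_recall():
    truth = {f"c{i}": "g1" for i in range(4)} | {f"d{i}": "g2" for i in range(4)}
    assignment = {c: 0 for c in truth if c.startswith("c")}
    assignment |= {c: 1 for c in truth if c.startswith("d")}
    assignment["d3"] = 0  # one contaminant in bin 0
    per_bin = evaluate_bins(_bins(assignment), truth)["per_bin"]
    assert per_bin[0]["precision"] == pytest.approx(4 / 5)
    assert per_bin[0]["recall"] == pytest.approx(1.0)
    assert per_bin[1]["recall"] == pytest.approx(3 / 4)


def test_empty_assignment_rejected():
    with pytest.raises(ValueError):
        evaluate_bins(BinAssignment(assignment={}, provenance={}), {})
    with pytest.raises(ValueError):
        evaluate_bins(_bins({"c": None}), {"c": "g1"})


def test_marker_quality_definitions():
    members = {f"c{i}": 0 for i in range(10)}
    bins = _bins(members)
    # 90 of 100 markers present once each
    markers = [(f"c{i % 10}", f"m{m:04d}") for m, i in zip(range(90), range(90))]
    (q,) = marker_quality(bins, markers, n_markers=100)
    assert q.completeness == pytest.approx(90.0)
    assert q.contamination == pytest.approx(0.0)


def test_marker_quality_counts_excess_copies():
    bins = _bins({"c0": 0})
    markers = [("c0", f"m{m:04d}") for m in range(100)]
    markers += [("c0", f"m{m:04d}") for m in range(5)]  # five duplicates
    (q,) = marker_quality(bins, markers, n_markers=100)
    assert q.completeness == pytest.approx(100.0)
    assert q.contamination == pytest.approx(5.0)


def test_bin_without_markers_scores_zero():
    bins = _bins({"c0": 0, "c1": 1})
    markers = [("c1", "m0001")]
    q0, q1 = marker_quality(bins, markers, n_markers=10)
    assert (q0.completeness, q0.contamination) == (0.0, 0.0)
    assert q1.completeness == pytest.approx(10.0)


def test_marker_quality_reports_sizes():
    bins = _bins({"c0": 0, "c1": 0})
    (q,) = marker_quality(bins, [], n_markers=5, contig_lengths={"c0": 1500, "c1": 2500})
    assert q.n_contigs == 2 and q.total_bp == 4000
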