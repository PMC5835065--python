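"""Bin quality scoring against simulation truth and planted markers.

Two complementary views: agreement of the recovered partition with the
generating genome labels (adjusted Rand index, per-bin precision/recall),
and the field's standard completeness/contamination pair computed from
planted single-copy markers — if a genome's markers are all present once in
a bin, the bin is complete and uncontaminated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from sklearn.metrics import adjusted_rand_score

from .binning import BinAssignment


@dataclass(frozen=True)
class BinQuality:
    """Marker-based quality of one bin (percent scales, as usually reported)."""

    bin_id: int
    completeness: float  # % of marker ids present at least once
    contamination: float  # % excess marker copies
    n_contigs: int
    total_bp: int


def evaluate_bins(bins: BinAssignment, truth: Mapping[str, str]) -> dict:
    """Score a bin assignment against the generating genome labels.

    Returns the adjusted Rand index over binned contigs, per-bin precision
    and recall under the majority-truth mapping, and the unbinned fraction.
    """
    if not bins.assignment:
        raise ValueError("empty bin assignment")
    missing = [c for c in bins.assignment if c not in truth]
    if missing:
        raise ValueError(f"truth labels missing for {len(missing)} contigs")

    binned = [(c, b) for c, b in bins.assignment.items() if b is not None]
    if not binned:
        raise ValueError("no binned contigs to evaluate")
    pred = [b for _, b in binned]
    true = [truth[c] for c, _ in binned]
    ari = float(adjusted_rand_score(true, pred))

    genome_sizes = Counter(truth[c] for c in bins.assignment)
    per_bin = {}
    for label, members in sorted(bins.bins().items()):
        counts = Counter(truth[c] for c in members)
        majority, hits = counts.most_common(1)[0]
        per_bin[label] = {
            "majority_genome": majority,
            "precision": hits / len(members),
            "recall": hits / genome_sizes[majority],
            "n_contigs": len(members),
        }
    return {
        "ari": ari,
        "per_bin": per_bin,
        "unbinned_fraction": len(bins.unbinned()) / len(bins.assignment),
    }


def marker_quality(bins: BinAssignment, markers: list[tuple[str, str]], n_markers: int,
                   contig_lengths: Mapping[str, int] | None = None) -> list[BinQuality]:
    """Completeness/contamination per bin from planted single-copy markers.

    completeness = 100 * (#distinct marker ids in the bin) / n_markers;
    contamination = 100 * (total marker copies - #distinct) / n_markers.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    by_contig: dict[str, list[str]] = {}
    for contig_id, marker_id in markers:
        by_contig.setdefault(contig_id, []).append(marker_id)

    out = []
    for label, members in sorted(bins.bins().items()):
        copies = [m for c in members for m in by_contig.get(c, [])]
        distinct = len(set(copies))
        total_bp = sum(contig_lengths[c] for c in members) if contig_lengths else 0
        out.append(BinQuality(
            bin_id=label,
            completeness=100.0 * distinct / n_markers,
            contamination=100.0 * (len(copies) - distinct) / n_markers,
            n_contigs=len(members),
            total_bp=total_bp,
        ))
    return out
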