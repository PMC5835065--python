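"""Contig binning from coverage embeddings, with composition and link refinement.

The pipeline order mirrors differential-coverage binning practice: cluster
contigs in the MDS embedding of their multi-sample coverage profiles, purge
composition outliers (GC / tetranucleotide signature) from each bin, then use
paired-end link evidence to recruit unbinned contigs and move mis-assigned
ones. Each stage is an explicit thresholded rule so the whole procedure is
reproducible — no visual/manual curation step survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .features import ContigFeatures
from .mds import Embedding
from .synthcom import LinkGraph

#: Assignment value for contigs outside every bin.
UNBINNED = None

Provenance = str  # "cluster" | "composition_removed" | "link_recruited" | "link_reassigned"


@dataclass
class BinAssignment:
    """Contig -> bin map with an explicit unbinned state.

    ``assignment[contig] is None`` means unbinned. ``provenance`` records the
    stage that last set each contig's state. Bin labels are contiguous
    integers starting at 0.
    """

    assignment: dict[str, int | None]
    provenance: dict[str, Provenance] = field(default_factory=dict)
    k: int | None = None
    silhouette: float | None = None
    degenerate: bool = False

    def bins(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for c, b in self.assignment.items():
            if b is not None:
                out.setdefault(b, []).append(c)
        return out

    def labels(self) -> set[int]:
        return {b for b in self.assignment.values() if b is not None}

    def unbinned(self) -> list[str]:
        return [c for c, b in self.assignment.items() if b is None]


# ---------------------------------------------------------------------------
# k-medoids clustering with silhouette model selection


def _kmedoids_once(D: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int = 200) -> tuple[np.ndarray, float]:
    """Voronoi-iteration k-medoids on a precomputed distance matrix."""
    n = D.shape[0]
    # distance-proportional (k-means++-style) seeding
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        dmin = D[:, medoids].min(axis=1)
        total = dmin.sum()
        if total <= 0:
            pool = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(pool)))
        else:
            medoids.append(int(rng.choice(n, p=dmin / total)))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            idx = np.flatnonzero(labels == c)
            if idx.size == 0:  # re-seed an empty cluster at the worst-served point
                far = int(np.argmax(D[np.arange(n), medoids[labels]]))
                new[c] = far
                continue
            within = D[np.ix_(idx, idx)].sum(axis=1)
            new[c] = int(idx[np.argmin(within)])
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = np.argmin(D[:, medoids], axis=1)
    cost = float(D[np.arange(n), medoids[labels]].sum())
    return labels, cost


def cluster_bins(emb: Embedding, contig_ids: list[str], k_min: int = 2, k_max: int = 16,
                 seed: int = 0, n_init: int = 5) -> BinAssignment:
    """Cluster embedded contigs; the bin count is chosen by mean silhouette.

    k-medoids is run for every k in [k_min, k_max] (``n_init`` seeded
    restarts each, best cost kept) and the k with maximal mean silhouette
    width wins; silhouette ties break towards smaller k. If all points
    coincide the geometry is degenerate (silhouette undefined): a single bin
    is returned with ``degenerate`` set.
    """
    n = len(contig_ids)
    if emb.coords.shape[0] != n:
        raise ValueError("embedding rows must match contig_ids")
    if not 2 <= k_min <= k_max < n:
        raise ValueError("need 2 <= k_min <= k_max < n contigs")

    D = squareform(pdist(emb.coords))
    if D.max() == 0.0:
        return BinAssignment(
            assignment={c: 0 for c in contig_ids},
            provenance={c: "cluster" for c in contig_ids},
            k=1, silhouette=None, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    best: tuple[float, int, np.ndarray] | None = None  # (silhouette, k, labels)
    for k in range(k_min, k_max + 1):
        run_best: tuple[float, np.ndarray] | None = None
        for _ in range(n_init):
            labels, cost = _kmedoids_once(D, k, rng)
            if run_best is None or cost < run_best[0]:
                run_best = (cost, labels)
        labels = run_best[1]
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        if best is None or sil > best[0] + 1e-12:  # ties keep the smaller k
            best = (sil, k, labels)
    if best is None:
        raise RuntimeError("clustering failed for every k in range")
    sil, k, labels = best
    # relabel to contiguous ints ordered by first appearance
    remap: dict[int, int] = {}
    assignment: dict[str, int | None] = {}
    for c, lab in zip(contig_ids, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignment[c] = remap[lab]
    return BinAssignment(
        assignment=assignment,
        provenance={c: "cluster" for c in contig_ids},
        k=k, silhouette=sil, degenerate=False,
    )


# ---------------------------------------------------------------------------
# composition refinement

_MAD_SCALE = 1.4826  # MAD -> sigma for normal data
_MIN_PRUNE_SIZE = 3  # bins smaller than this carry too little statistics to prune


def refine_by_composition(bins: BinAssignment, feats: dict[str, ContigFeatures],
                          z_max: float = 3.0) -> BinAssignment:
    """Unbin contigs whose composition is a robust outlier within their bin.

    Per bin the medians of GC and of the TNF vector are taken; a contig is
    removed when its GC deviation or its Euclidean TNF distance to the bin
    median exceeds ``z_max`` robust (MAD-scaled) deviations. Bins with fewer
    than three contigs are never pruned. The operation only removes — it
    never adds contigs to a bin and never renames bins.
    """
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    assignment = dict(bins.assignment)
    provenance = dict(bins.provenance)
    for label, members in bins.bins().items():
        if len(members) < _MIN_PRUNE_SIZE:
            continue
        for c in members:
            if c not in feats:
                raise ValueError(f"no features for binned contig {c}")
        gc = np.array([feats[c].gc for c in members])
        tnf = np.vstack([feats[c].tnf for c in members])

        gc_med = np.median(gc)
        gc_mad = _MAD_SCALE * np.median(np.abs(gc - gc_med))
        tnf_med = np.median(tnf, axis=0)
        d = np.linalg.norm(tnf - tnf_med, axis=1)
        d_med = np.median(d)
        d_mad = _MAD_SCALE * np.median(np.abs(d - d_med))

        for i, c in enumerate(members):
            out = False
            if gc_mad > 0 and abs(gc[i] - gc_med) / gc_mad > z_max:
                out = True
            if d_mad > 0 and (d[i] - d_med) / d_mad > z_max:
                out = True
            if out:
                assignment[c] = UNBINNED
                provenance[c] = "composition_removed"
    refined = BinAssignment(assignment=assignment, provenance=provenance,
                            k=bins.k, silhouette=bins.silhouette, degenerate=bins.degenerate)
    return refined


# ---------------------------------------------------------------------------
# paired-end link recruitment


def recruit_by_links(bins: BinAssignment, links: LinkGraph, add_frac: float = 0.5,
                     reassign_frac: float = 0.7, min_links: int = 2) -> BinAssignment:
    """Recruit or move contigs according to paired-end link majorities.

    Decisions are made in one pass, in lexicographic contig order, against
    the frozen pre-pass assignment (no cascading). An unbinned contig joins
    bin b when its links to b strictly exceed ``add_frac`` of its total link
    count (and the total is at least ``min_links``); a binned contig moves to
    another bin holding at least ``reassign_frac`` of its links under the
    same total floor.
    """
    if not 0.5 <= add_frac <= reassign_frac <= 1.0:
        raise ValueError("need 0.5 <= add_frac <= reassign_frac <= 1")
    if min_links < 1:
        raise ValueError("min_links must be >= 1")

    incident: dict[str, list[tuple[str, int]]] = {}
    for a, b, n in links.edges:
        incident.setdefault(a, []).append((b, n))
        incident.setdefault(b, []).append((a, n))

    pre = bins.assignment  # frozen state all decisions read from
    assignment = dict(pre)
    provenance = dict(bins.provenance)
    for c in sorted(pre):
        neigh = incident.get(c, [])
        total = sum(n for _, n in neigh)
        if total < min_links:
            continue
        to_bin: dict[int, int] = {}
        for other, n in neigh:
            b = pre.get(other)
            if b is not None:
                to_bin[b] = to_bin.get(b, 0) + n
        if not to_bin:
            continue
        current = pre[c]
        if current is UNBINNED:
            b_best, n_best = max(to_bin.items(), key=lambda kv: (kv[1], -kv[0]))
            if n_best > add_frac * total:
                assignment[c] = b_best
                provenance[c] = "link_recruited"
        else:
            candidates = {b: n for b, n in to_bin.items() if b != current}
            if not candidates:
                continue
            b_best, n_best = max(candidates.items(), key=lambda kv: (kv[1], -kv[0]))
            if n_best >= reassign_frac * total:
                assignment[c] = b_best
                provenance[c] = "link_reassigned"
    return BinAssignment(assignment=assignment, provenance=provenance,
                         k=bins.k, silhouette=bins.silhouette, degenerate=bins.degenerate)
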