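"""Synthetic metagenome communities with known ground truth.

Emulates the inputs of multi-timepoint differential-coverage binning for a
small nitrifying enrichment community: K genomes, each with its own
composition signature (an order-k Markov sequence model biased towards a
target GC), fragmented into contigs above an assembly length floor; a
per-contig, per-sample coverage matrix following per-genome abundance
trajectories with multiplicative lognormal noise; intra-genome paired-end
links with a configurable spurious-link fraction; and planted single-copy
markers used for completeness/contamination scoring.

Mean depths are simulated directly; read-level simulation and mapping are
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .coverage import CoverageMatrix

#: Default mean-depth trajectories for the 8-genome, 3-timepoint community.
#: The first two rows are the nitrifier-like genomes (ammonia oxidiser and
#: nitrite oxidiser), most abundant at the middle time point; the rest are
#: background heterotrophs with assorted dynamics (decaying, late-blooming,
#: stable, crashing/rebounding, slowly rising, fading).
DEFAULT_TRAJECTORIES_8x3: tuple[tuple[float, ...], ...] = (
    (20.0, 90.0, 35.0),
    (8.0, 45.0, 18.0),
    (80.0, 40.0, 15.0),
    (15.0, 30.0, 70.0),
    (50.0, 55.0, 50.0),
    (90.0, 15.0, 55.0),
    (6.0, 12.0, 40.0),
    (35.0, 10.0, 8.0),
)

#: Default GC targets; the nitrifier-like genomes sit near Nitrosomonas
#: (~0.48) and Nitrobacter (~0.62) values.
DEFAULT_GC_8: tuple[float, ...] = (0.48, 0.62, 0.38, 0.44, 0.52, 0.56, 0.66, 0.42)

_ALPHABET = "ACGT"


def default_trajectories(n_genomes: int, n_timepoints: int) -> list[list[float]]:
    """Deterministic default abundance trajectories.

    For the canonical 8x3 design the hand-set table above is used; otherwise
    genomes get staggered Gaussian-bump profiles with geometrically spaced
    magnitudes, which keeps profiles pairwise distinct.
    """
    if n_genomes == 8 and n_timepoints == 3:
        return [list(row) for row in DEFAULT_TRAJECTORIES_8x3]
    t = np.arange(n_timepoints, dtype=float)
    out = []
    for g in range(n_genomes):
        peak = (g * max(1, n_timepoints // 2 + 1)) % n_timepoints
        base = 12.0 * 1.45**g
        prof = base * (0.2 + 0.8 * np.exp(-0.5 * ((t - peak) / 0.8) ** 2))
        out.append(prof.tolist())
    return out


def default_gc_targets(n_genomes: int) -> list[float]:
    if n_genomes == 8:
        return list(DEFAULT_GC_8)
    return list(np.linspace(0.36, 0.64, n_genomes))


class CommunityConfig(BaseModel):
    """Parameters of one synthetic community draw.

    ``contig_min_bp``/``contig_mean_bp`` define the contig length law
    (shifted exponential with a hard floor, defaults matching a 1.2 kb
    assembly minimum). ``abundance_trajectories[g][t]`` is the expected mean
    depth of genome ``g`` at time point ``t``.
    """

    model_config = ConfigDict(extra="forbid")

    n_genomes: int = 8
    genome_length_bp: int = 150_000
    contig_min_bp: int = 1_200
    contig_mean_bp: int = 3_000
    n_timepoints: int = 3
    abundance_trajectories: list[list[float]] | None = None
    coverage_noise_cv: float = 0.2
    links_per_contig: float = 3.0
    spurious_link_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    n_markers: int = 100
    gc_targets: list[float] | None = None
    composition_order: int = 3
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CommunityConfig":
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.genome_length_bp <= 0 or self.contig_min_bp <= 0:
            raise ValueError("lengths must be positive")
        if self.contig_mean_bp <= self.contig_min_bp:
            raise ValueError("contig_mean_bp must exceed contig_min_bp")
        if self.genome_length_bp < self.contig_min_bp:
            raise ValueError("genome shorter than the contig length floor")
        if self.coverage_noise_cv < 0:
            raise ValueError("coverage_noise_cv must be >= 0")
        if self.links_per_contig < 0:
            raise ValueError("links_per_contig must be >= 0")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not 1 <= self.composition_order <= 6:
            raise ValueError("composition_order must be in [1, 6]")
        if self.abundance_trajectories is not None:
            traj = self.abundance_trajectories
            if len(traj) != self.n_genomes or any(len(r) != self.n_timepoints for r in traj):
                raise ValueError("abundance_trajectories must be n_genomes x n_timepoints")
            if any(v <= 0 for row in traj for v in row):
                raise ValueError("every abundance trajectory entry must be strictly positive")
        if self.gc_targets is not None:
            if len(self.gc_targets) != self.n_genomes:
                raise ValueError("gc_targets must have one entry per genome")
            if any(not 0 < g < 1 for g in self.gc_targets):
                raise ValueError("gc_targets must lie in (0, 1)")
        return self

    def resolved_trajectories(self) -> np.ndarray:
        traj = self.abundance_trajectories or default_trajectories(
            self.n_genomes, self.n_timepoints
        )
        return np.asarray(traj, dtype=float)

    def resolved_gc(self) -> list[float]:
        return list(self.gc_targets) if self.gc_targets is not None else default_gc_targets(
            self.n_genomes
        )


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    sequence: str
    genome: str | None  # simulation truth label; None for real data


@dataclass
class ContigSet:
    """Contigs plus (for simulated data) truth labels and marker placements."""

    records: list[ContigRecord]
    markers: list[tuple[str, str]] = field(default_factory=list)  # (contig_id, marker_id)

    def __post_init__(self) -> None:
        ids = [r.contig_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("contig ids must be unique")

    @property
    def contig_ids(self) -> list[str]:
        return [r.contig_id for r in self.records]

    def truth(self) -> dict[str, str]:
        return {r.contig_id: r.genome for r in self.records if r.genome is not None}

    def by_genome(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.records:
            if r.genome is not None:
                out.setdefault(r.genome, []).append(r.contig_id)
        return out

    def lengths(self) -> dict[str, int]:
        return {r.contig_id: len(r.sequence) for r in self.records}


@dataclass
class LinkGraph:
    """Unordered paired-end link counts between contigs (no self-edges)."""

    edges: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        for a, b, n in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a}")
            if n < 1:
                raise ValueError("link counts must be >= 1")


# ---------------------------------------------------------------------------
# sequence model


def _tilted_transitions(order: int, gc_target: float, rng: np.random.Generator) -> np.ndarray:
    """Random per-context transition probabilities tilted towards a GC target.

    Each of the 4^order contexts gets an independent Dirichlet draw (this is
    what gives every genome its own tetranucleotide signature); C/G columns
    are then reweighted so the chain's average GC lands near the target.
    """
    n_ctx = 4**order
    probs = rng.dirichlet([1.5, 1.5, 1.5, 1.5], size=n_ctx)
    f = gc_target / (1.0 - gc_target)
    w = np.array([1.0, f, f, 1.0])
    tilted = probs * w
    return tilted / tilted.sum(axis=1, keepdims=True)


def _markov_sequence(trans: np.ndarray, order: int, length: int,
                     rng: np.random.Generator) -> str:
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    ctx = 0
    n_ctx = trans.shape[0]
    cum_list = cum  # local alias
    for i in range(length):
        row = cum_list[ctx]
        ui = u[i]
        b = 0 if ui < row[0] else 1 if ui < row[1] else 2 if ui < row[2] else 3
        out[i] = b
        ctx = (ctx * 4 + b) % n_ctx
    return "".join(_ALPHABET[b] for b in out)


def _genome_sequence(order: int, gc_target: float, length: int,
                     rng: np.random.Generator) -> str:
    trans = _tilted_transitions(order, gc_target, rng)
    # one correction round: measure GC on a probe and re-tilt
    probe = _markov_sequence(trans, order, min(20_000, max(4_000, length // 10)), rng)
    gc_obs = (probe.count("G") + probe.count("C")) / len(probe)
    gc_obs = min(max(gc_obs, 0.01), 0.99)
    adjust = (gc_target / (1 - gc_target)) / (gc_obs / (1 - gc_obs))
    w = np.array([1.0, adjust, adjust, 1.0])
    trans = trans * w
    trans /= trans.sum(axis=1, keepdims=True)
    return _markov_sequence(trans, order, length, rng)


def _fragment(length: int, min_bp: int, mean_bp: int, rng: np.random.Generator) -> list[int]:
    """Cut a genome into contig lengths: shifted exponential with floor."""
    cuts: list[int] = []
    pos = 0
    while length - pos >= min_bp:
        size = min_bp + int(rng.exponential(mean_bp - min_bp))
        if length - pos - size < min_bp:
            size = length - pos  # absorb the tail so no fragment drops below floor
        cuts.append(size)
        pos += size
    return cuts


# ---------------------------------------------------------------------------
# generator


def plant_markers(contigs: ContigSet, n_markers: int, seed: int) -> ContigSet:
    """Plant ``n_markers`` single-copy markers per truth genome.

    Each (genome, marker) pair is placed on exactly one of the genome's
    contigs, uniformly at random; a contig may carry several markers.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = np.random.default_rng(seed)
    by_genome = contigs.by_genome()
    if not by_genome:
        raise ValueError("no truth-labelled contigs to plant markers on")
    placements: list[tuple[str, str]] = []
    for genome in sorted(by_genome):
        ids = by_genome[genome]
        if not ids:
            raise ValueError(f"genome {genome} has no contigs")
        choice = rng.integers(0, len(ids), size=n_markers)
        for m, c in enumerate(choice, start=1):
            placements.append((ids[c], f"m{m:04d}"))
    return ContigSet(records=list(contigs.records), markers=placements)


def generate_community(config: CommunityConfig) -> tuple[ContigSet, CoverageMatrix, LinkGraph]:
    """Draw one labelled community: contigs, coverage matrix and link graph.

    Deterministic for a fixed config (including seed). The expected coverage
    of every contig of genome g at time t equals
    ``abundance_trajectories[g][t]``; the observed value multiplies it by
    lognormal noise with the configured CV. With ``spurious_link_rate == 0``
    every link joins two contigs of the same genome.
    """
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(4)
    rng_seq = np.random.default_rng(seeds[0])
    rng_cov = np.random.default_rng(seeds[1])
    rng_link = np.random.default_rng(seeds[2])
    marker_seed = int(np.random.default_rng(seeds[3]).integers(0, 2**31 - 1))

    traj = config.resolved_trajectories()
    gc = config.resolved_gc()

    records: list[ContigRecord] = []
    contig_genome_idx: list[int] = []
    for g in range(config.n_genomes):
        genome_id = f"genome{g + 1:02d}"
        seq = _genome_sequence(config.composition_order, gc[g], config.genome_length_bp, rng_seq)
        pos = 0
        for j, size in enumerate(
            _fragment(config.genome_length_bp, config.contig_min_bp, config.contig_mean_bp, rng_seq)
        ):
            records.append(
                ContigRecord(f"{genome_id}_c{j + 1:04d}", seq[pos:pos + size], genome_id)
            )
            contig_genome_idx.append(g)
            pos += size

    contig_ids = [r.contig_id for r in records]
    genome_idx = np.asarray(contig_genome_idx)
    n_contigs = len(records)

    # coverage: expected depth per contig follows its genome's trajectory
    expected = traj[genome_idx, :]
    cv = config.coverage_noise_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        noise = rng_cov.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=expected.shape)
    else:
        noise = 1.0
    samples = [f"t{t + 1}" for t in range(config.n_timepoints)]
    cov = CoverageMatrix(contig_ids, samples, expected * noise)

    # paired-end links: mostly intra-genome, a configurable fraction spurious
    members: dict[int, np.ndarray] = {
        g: np.flatnonzero(genome_idx == g) for g in range(config.n_genomes)
    }
    tallies: dict[tuple[int, int], int] = {}
    n_events = rng_link.poisson(config.links_per_contig, size=n_contigs)
    for i in range(n_contigs):
        for _ in range(int(n_events[i])):
            if config.spurious_link_rate > 0 and rng_link.random() < config.spurious_link_rate:
                j = int(rng_link.integers(0, n_contigs))
                while j == i:
                    j = int(rng_link.integers(0, n_contigs))
            else:
                mates = members[int(genome_idx[i])]
                if mates.size < 2:
                    continue
                j = i
                while j == i:
                    j = int(mates[rng_link.integers(0, mates.size)])
            key = (i, j) if i < j else (j, i)
            tallies[key] = tallies.get(key, 0) + 1
    edges = [
        (contig_ids[i], contig_ids[j], n) for (i, j), n in sorted(tallies.items())
    ]
    links = LinkGraph(edges=edges)

    contigs = plant_markers(ContigSet(records=records), config.n_markers, marker_seed)
    return contigs, cov, links
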