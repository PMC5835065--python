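# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limits of what the test suite shows. All empirical numbers
mentioned here are computed by the examples, tests or acceptance script.

## Differential-coverage binning

**Signal.** The binner's primary signal is a contigs × samples matrix of mean
per-base depths. Contigs from one genome share an abundance trajectory, so
in a suitable geometry they form one cluster per genome. Composition (GC,
tetranucleotide frequencies) and paired-end links are secondary signals used
only to refine, never to seed, the clusters.

**Coverage transform.** Columns are scaled so all column sums equal the
largest column sum (equalising sequencing effort per sample), then mapped
through log10(x + 1). Depth noise is multiplicative, so distances on the
log scale are the natural choice; the pseudocount of 1 keeps zero-depth
contigs finite and is negligible against typical depths of 10–100×.

**Embedding.** Classical (Torgerson) scaling of squared Euclidean distances:
double-centre, eigendecompose, scale eigenvectors by √eigenvalues. Negative
eigenvalues are clamped to zero; when fewer than d meaningfully positive
eigenvalues exist (relative threshold 1e-12) the missing columns are zero
and the embedding is flagged rank-deficient. For Euclidean inputs the
embedding is exact to machine precision, which the tests verify against a
direct distance oracle and against an independent principal-coordinates
implementation.

**Dimensionality.** Default d = min(3, number of samples). With three
time points the coverage profile is 3-dimensional; dropping to 2 axes can
collapse genome pairs whose trajectory difference lies along the discarded
axis, and keeping all informative axes costs nothing at these sizes.

**Clustering.** k-medoids (Voronoi iteration, distance-proportional seeding,
5 restarts per k) on the embedding for every k in [2, 16]; the k with the
highest mean silhouette wins, ties towards smaller k. k-medoids is robust to
the elongated clusters the log transform can leave and is deterministic
under the seed. If all points coincide the silhouette is undefined: a single
bin is returned with a degenerate-geometry flag.

**Composition refinement.** Per bin, the medians of GC and of the TNF vector
are taken; a contig is unbinned if its GC deviation or its Euclidean TNF
distance to the median exceeds 3 robust deviations (MAD × 1.4826). Bins of
fewer than 3 contigs are never pruned. The stage is strictly conservative:
it removes, never adds or renames. Because TNF noise grows on short contigs,
the MAD rule removes a small fraction of genuine members; the link stage
recruits them back, which is why refinement runs before recruitment.

**Link recruitment.** One pass in lexicographic contig order against the
frozen pre-pass assignment (no cascades): an unbinned contig joins a bin
holding strictly more than 50% of its link weight (total ≥ 2 links); a
binned contig moves to a bin holding ≥ 70% of its link weight. Counting all
incident links — including those to unbinned neighbours — in the denominator
makes the rule strictly harder to satisfy, which is the conservative choice
given that spurious links exist.

**Scoring.** Adjusted Rand index over binned contigs (chance-corrected
partition agreement), per-bin precision/recall under the majority-truth
mapping, and the completeness/contamination pair over planted single-copy
markers: completeness = % of marker ids present at least once, contamination
= % excess copies. This is a planted-truth simplification of lineage-specific
marker-set tools, appropriate because the markers are planted by the
generator rather than inferred from a reference database.

## Synthetic community generator

The generator emulates the statistical structure the binner assumes, with
every contig labelled by its source genome.

* **Sequences.** Per genome, an order-3 Markov chain whose per-context
  transition probabilities are independent Dirichlet draws tilted towards
  the genome's GC target (one probe-and-correct round lands the realised GC
  within ~0.01 of target). Independent transition tables give each genome a
  distinct tetranucleotide signature, which the refinement stage needs.
* **Contigs.** Shifted-exponential lengths with a hard 1.2 kb floor
  (mean 3 kb), cut sequentially from each 150 kb genome (~50 contigs per
  genome, ~400 total). These sizes keep a full pipeline run around a second
  while leaving enough contigs per bin for robust statistics.
* **Abundance.** The default community is 8 genomes × 3 time points. The two
  nitrifier-like genomes peak at the middle time point; the background
  genomes decay, bloom late, stay flat, crash and rebound, rise slowly, or
  fade — a spread of dynamics chosen so profiles are pairwise distinct on
  the log scale, as in a community whose members respond differently to
  enrichment. Observed depth = trajectory value × lognormal noise with
  CV 0.2 (mean 1).
* **Links.** Per contig, Poisson(3) link events to uniform genome-mates; a
  2% fraction is spurious, with endpoints uniform over all contigs — the
  worst-case confounder for recruitment.
* **Markers.** 100 marker ids per genome, each placed on exactly one
  uniformly chosen contig of that genome. Marker ids are shared across
  genomes, so a foreign contig's markers appear as duplicate copies
  (contamination) in the receiving bin.
* **GC targets.** 0.38–0.66 with the nitrifier-like genomes near 0.48
  (*Nitrosomonas*-like) and 0.62 (*Nitrobacter*-like).

What the generator does **not** emulate: read-level errors, chimeric or
repeat-collapsed contigs, strain microdiversity, inter-genome shared
sequence, and assembly-graph artefacts. Passing tests therefore show the
algorithmic chain is correct under its stated noise model, not that it
would resolve strain mixtures in real assemblies.

## Growth kinetics

**Window rule.** Among all contiguous windows of ≥ 4 positive measurements,
keep those whose ln(series)-vs-time OLS has positive slope and R² ≥ 0.99;
the longest wins, ties towards the earliest start. The search is exhaustive
via prefix sums (O(n²) windows at O(1) each). Zeros are excluded as
below-detection readings, not data; windows with numerically zero response
variance (< 1e-12 on the ln scale) are flat and are never accepted, whatever
round-off does to their slope sign. Natural log is used so the slope *is* μ.

**Lag.** Window start minus inoculation time; shifting the time axis shifts
lag exactly.

**Monod fit.** Bounded trust-region nonlinear least squares (positive
parameters, tolerances 1e-15) initialised at μ_max⁰ = max μ and K_s⁰ = the
S nearest μ_max⁰/2. Noiseless self-consistency is exact to ~1e-6 relative;
under 5% multiplicative noise on the 5-point grid the median K_s error is
well inside 25%, and the error shrinks as replicates accumulate. Degenerate
inputs (single concentration, all-zero rates) are rejected; non-convergence
returns the best iterate flagged, so a poorly fitting culture yields
diagnostics rather than a silent failure.

**Kinetics pipeline design.** Simulated dose–response experiments pair each
bottle's fitted μ with the **mean substrate concentration over its
regression window** rather than the nominal initial concentration, and the
experiment design includes two realistic features that keep the regression
in the truly exponential regime: readings below a 2 μM detection limit are
recorded as 0 (censored), and a bottle is harvested once substrate drawdown
exceeds 20% (initial-rate design). With the default small inoculum (0.01 μM
substrate-equivalent of biomass) these choices bound the slope bias; the
noiseless grid recovers K_s within 1%. Without them, the longest-window
rule happily spans the approach-to-exponential bend and the depletion bend
— R² ≥ 0.99 is a weak constraint over several ln-units of dynamic range —
and K_s estimates degrade by an order of magnitude.

**qPCR.** OLS line Ct vs log10(copies); unknowns inverted through the line;
efficiency = 10^(−1/slope) − 1. Requires ≥ 3 standards spanning ≥ 2 decades
and a negative slope.

## Two-guild cascade simulator

State (X_A, X_B, NH₄, NO₂, NO₃); each guild is switched on at its lag time
and grows at its Monod rate on its substrate; substrate conversion is growth
over a fixed yield, so d(NH₄+NO₂+NO₃)/dt = 0 identically and RK4 preserves
the sum to round-off — an exactly testable invariant bought by neglecting
nitrogen assimilation into biomass. Fixed-step RK4 at dt = 0.25 h; halving
dt moves terminal concentrations by < 1e-4 μM. A state excursion below
−1e-9 aborts with a message naming dt. Measurement noise (lognormal,
mean 1) is applied to returned samples only, never to the state.

The hard lag switch is the simplest mechanism matching an operational lag
definition (time to the first regression point); smooth adjustment models
would blur the planted lag the tests check. Bicarbonate amendment is a
scalar multiplier on both μ_max values — no carbon-limitation law is
modelled. Yields, initial biomasses and the NOB parameters are not
constrained by any printed value; the defaults (Y = 0.01 per μM, X_A0 = 0.5,
μ_max_B = 0.04 h⁻¹, K_B = 12 μM, lag_B = 35 h) were chosen once so the
coupled 500 μM culture completes within ~120–200 h with a strictly interior
nitrite peak, the qualitative template of the coupled-culture experiment.

## Orchestration and reproducibility

A single global seed expands to per-stage seeds as
(seed × 1000 + stage) mod 2³¹ (community = 0, clustering = 1, kinetics
bottle i = 10 + i), so any stage can be re-run in isolation. Run directories
contain the resolved config, a fixed-format log (no timestamps), and all
tables; re-running with the same config and seed is byte-identical. Genomic
tables are TSV, chemistry tables CSV, contigs FASTA; headers are mandatory.

## Known limitations

* The binner assumes mean-depth coverage; read-count coverage would need a
  length correction upstream.
* Silhouette-based model selection can merge genomes whose trajectories are
  nearly parallel on the log scale; the default community is constructed to
  avoid this, real communities are not.
* The window selector's R² floor is a weak curvature constraint on densely
  sampled, wide-dynamic-range series; the kinetics pipeline's censoring and
  harvest rules exist precisely to keep it meaningful.
* The cascade neglects pH speciation, oxygen, inhibition and comammox-style
  complete oxidisers; it is a stand-in with the right stoichiometry and
  timing, not a mechanistic digestor model.
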