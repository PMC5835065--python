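# nitrosyn

Differential-coverage genome binning and nitrification growth kinetics,
exercised end to end on synthetic freshwater-nitrifier communities with
known ground truth.

## The problem

Nitrification in freshwater systems is carried out by two bacterial guilds:
ammonia oxidisers (AOB, NH₄⁺ → NO₂⁻) and nitrite oxidisers (NOB,
NO₂⁻ → NO₃⁻). Studying their partnership in enrichment cultures combines
two computations that this package implements as a reusable, fully tested
library:

1. **Multi-timepoint differential-coverage binning.** Contigs assembled from
   a community metagenome are grouped into draft genomes using their
   coverage trajectories across time-series samples (contigs from one genome
   rise and fall together). Coverage profiles are depth-normalised,
   log₁₀-transformed, embedded with classical (Torgerson) MDS and clustered
   with k-medoids (bin count chosen by mean silhouette). Bins are then
   refined by sequence composition — GC content and canonical
   tetranucleotide frequencies (136 strand-collapsed 4-mers) — and polished
   with paired-end link evidence that recruits unbinned contigs and moves
   mis-assigned ones. Quality is scored as the standard
   completeness/contamination pair over planted single-copy markers, and as
   the adjusted Rand index against the generating genome labels.

2. **Nitrification growth kinetics.** A nitrifier population's growth is read
   from the chemistry it drives: the specific growth rate μ (h⁻¹) is the
   slope of ln(oxidation product) against time over the exponential phase
   (product = NO₂⁻ + NO₃⁻ for AOB, NO₃⁻ for NOB). The exponential window is
   selected algorithmically as the longest run of positive measurements
   whose log-linear regression has positive slope and R² ≥ 0.99; lag is the
   time from inoculation to the window start. Substrate dependence follows
   the Monod model μ = μ_max · S / (K_s + S), fitted by bounded nonlinear
   least squares. qPCR gene-copy quantification against a serial-dilution
   standard curve is included.

Because real deposited sequencing data are deliberately not required, the
package ships first-class synthetic-data generators: a labelled community
simulator (Markov-chain genome sequences with per-genome GC targets,
fragmenting into ≥1.2 kb contigs, lognormal multiplicative coverage noise,
intra-genome paired-end links with a spurious fraction, planted markers)
and a two-guild Monod cascade ODE simulator (RK4) whose nitrogen balance is
conserved exactly by construction.

## Worked example

```sh
python examples/bin_community.py
```

```
chosen k: 8 bins (mean silhouette 0.661)
adjusted Rand index vs truth: 1.0000
unbinned fraction: 0.000

 bin  contigs    Mbp  completeness  contamination
   0       52   0.15        100.0%           0.0%
   ...
   7       53   0.15        100.0%           0.0%
```

The default 8-genome, 3-timepoint community is resolved into exactly eight
bins that coincide with the generating genomes (ARI 1.0); every bin holds
all 100 of its genome's planted markers exactly once (completeness 100%,
contamination 0%).

```sh
python examples/growth_kinetics.py
```

```
  S0 (μM)  S in window   μ (1/h)       R²  lag (h)
       50         45.0   0.01784   0.9999      312
      200        187.1   0.02465   1.0000      238
      500        474.9   0.02659   1.0000      224
     1000        956.0   0.02729   1.0000      218
     1500       1441.4   0.02753   1.0000      216

Monod fit: mu_max = 0.02803 1/h, Ks = 25.70 μM (converged=True)
```

Five simulated bottles across the 50–1500 μM NH₄⁺ grid: μ saturates with
substrate and the Monod fit recovers the simulator's parameters
(μ_max 0.028 h⁻¹, K_s 25.9 μM) to within a percent. The other examples
(`simulate_community.py`, `cascade_cultures.py`, `qpcr_quantification.py`)
cover the generator, the three culture configurations of the cascade, and
qPCR quantification.

A thin CLI wraps the same pipelines:

```sh
nitrosyn run-binning --out run/ --seed 11
nitrosyn run-kinetics --out kin/ --seed 3
nitrosyn sim-community --out sim/ --seed 7
nitrosyn bin --contigs sim/contigs.fasta --coverage sim/coverage.tsv --links sim/links.tsv --out bins.tsv
```

Every run writes its resolved configuration next to the outputs and is
byte-reproducible from the single seed.

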