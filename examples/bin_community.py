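"""Full binning pipeline on a synthetic community, scored against truth.

Coverage profiles are depth-normalised, log-transformed, embedded with
classical MDS, clustered by k-medoids (bin count chosen by silhouette),
purged of composition outliers and polished with paired-end links. Truth
labels and planted single-copy markers then score the result.
"""

from nitrosyn import RunConfig, run_binning_pipeline

report = run_binning_pipeline(RunConfig(seed=11))

print(f"chosen k: {report['k']} bins (mean silhouette {report['silhouette']:.3f})")
print(f"adjusted Rand index vs truth: {report['ari']:.4f}")
print(f"unbinned fraction: {report['unbinned_fraction']:.3f}")
print(f"\n{'bin':>4}{'contigs':>9}{'Mbp':>7}{'completeness':>14}{'contamination':>15}")
for q in report["quality"]:
    print(f"{q['bin_id']:>4}{q['n_contigs']:>9}{q['total_bp'] / 1e6:>7.2f}"
          f"{q['completeness']:>13.1f}%{q['contamination']:>14.1f}%")

print("\nARI 1.0 means the recovered bins coincide with the generating genomes; "
      "completeness/contamination come from the planted single-copy markers "
      "(100/0 is a perfect draft genome).")
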