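"""Statistical comparison of graph metrics between the two frequency bands.

Runs the full pipeline on a synthetic cohort at the default study conditions
(28 subjects), computing per-subject modularity Q and global
efficiency E for each band at five sparsity thresholds, then compares the
bands cell-by-cell with paired two-tailed t-tests corrected jointly over the
10 comparisons with the Benjamini-Yekutieli FDR."""

import freqconn as fc
from freqconn.pipeline import analyze_cohort
from freqconn.synthetic import planted_bands

cfg = fc.GeneratorConfig(n_subjects=28, seed=0)
panels = fc.generate_cohort(cfg)
result = analyze_cohort(panels, planted_bands(cfg), n_restarts=40, seed=1)

table = result.comparison.table
print(table[["metric", "sparsity", "t", "p", "significant"]].to_string(index=False))
n_mod = int(table[table.metric == "modularity"]["significant"].sum())
n_eff = int(table[table.metric == "efficiency"]["significant"].sum())
print(f"\nmodularity is higher in the lower band (flagged in {n_mod}/5 cells);")
print(f"efficiency is flagged in {n_eff}/5 cells: the integration difference, "
      "if any, sits at the detection boundary at this sample size.")
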