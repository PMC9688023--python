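"""Simulate a genotype panel with an additive trait, then quality-control it.

Builds a small version of the benchmark structure (multi-chromosome SNP panel,
reference/validation generations, a trait of known heritability), writes it as
a PLINK binary triple, reads it back, and applies the standard QC filters.
"""

import numpy as np

from gptk import (
    QCParams,
    SimConfig,
    qc_filter,
    read_plink,
    simulate_dataset,
    write_plink,
)

cfg = SimConfig(
    n_individuals=500,
    n_markers=1000,
    n_chromosomes=5,
    n_qtl=60,
    heritability=0.45,
    n_reference=400,
    seed=1,
)
g, y, truth = simulate_dataset(cfg)
print(f"panel: {g.n_individuals} individuals x {g.n_markers} markers, "
      f"{cfg.n_chromosomes} chromosomes")
print(f"trait: {cfg.n_qtl} QTL, target h2 = {cfg.heritability}, "
      f"realized h2 = {truth.realized_h2:.3f}")

write_plink(g, "scratch_example_panel")
g_back = read_plink("scratch_example_panel")
assert np.array_equal(g.dosages, g_back.dosages)
print("PLINK .bed/.bim/.fam round trip: identical dosages")

g_qc, y_qc, report = qc_filter(g, y, QCParams(
    max_missing_per_individual=0.10, min_maf=0.05, min_call_rate=0.95,
    hwe_p_threshold=1e-6,
))
print(f"QC: kept {report.retained_dims[0]} individuals x "
      f"{report.retained_dims[1]} markers; removed per rule: "
      f"{report.n_markers_removed_by_rule}")
# Markers removed here are rare-allele markers (MAF < 5%); the simulated
# panel has no missingness or HWE violations, so those counters stay at 0.
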