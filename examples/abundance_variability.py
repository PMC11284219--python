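"""Quantify how workflow autonomy inflates between-run abundance variability.

For every genus, the Log2 fold-change of its CPM abundance in each
(run, library) is computed against the averaged primary-lab baseline; the
per-genus *range* of those Log2FC values across runs measures how much
laboratories disagree.  Comparing the mean range across the three library
autonomy levels (Seq < PCR/Seq < Ext/PCR/Seq) shows variability growing
with every extra step the secondary lab performs itself.
"""

from seqrunqc import (
    SyntheticConfig,
    aggregate_to_rank,
    build_taxonomy,
    cpm_normalize,
    log2fc_range,
    log2fc_vs_reference,
    rm_anova_variability,
    simulate_study,
)

config = SyntheticConfig(seed=2)
table, metadata, _, truth = simulate_study(config)
lineage = build_taxonomy(config)
meta = metadata.data
soil_ids = list(meta.index[meta["sample_type"] == "soil"])

for rank in ("phylum", "genus"):
    agg = aggregate_to_rank(table, lineage, rank)
    cpm = cpm_normalize(agg.subset_samples(soil_ids))
    lfc = log2fc_vs_reference(cpm, metadata, truth.reference_runs)
    result = rm_anova_variability(log2fc_range(lfc), rank=rank)
    print(f"{rank}-level mean Log2FC range (95% CI) per library:")
    for lib in result.mean_ranges.index:
        print(f"  {lib:12s} {result.mean_ranges[lib]:.2f} "
              f"({result.ci_low[lib]:.2f}-{result.ci_high[lib]:.2f})")
    print(f"  RM-ANOVA: F = {result.f_statistic:.1f}, "
          f"p = {result.p_value:.2g} (GG eps = {result.gg_epsilon:.2f})\n")

print("Ranges rise with autonomy (Seq < PCR/Seq < Ext/PCR/Seq) and are larger "
      "at finer ranks, where per-taxon counts are smaller and noisier.")
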