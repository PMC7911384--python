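"""Consensus reconstruction and within-group diversity.

Calls a consensus mitogenome from mapped reads (depth ≥ 3, 50%
plurality), anchors it with the panel references into a multiple
alignment, strips the control region and every gap/N column, and
computes site classes and pairwise differences.
"""

from paleomito import (
    MapConfig,
    PanelSpec,
    ReadSimParams,
    SeedIndex,
    anchor_msa,
    call_consensus,
    classify_sites,
    dedup,
    filter_mapq,
    generate_panel,
    map_reads,
    pairwise_diffs,
    sequence_identity,
    simulate_reads,
    strip_columns,
)

sim = generate_panel(PanelSpec(n_refs=4, ref_length=8_000, pairwise_divergence=0.04, seed=7))
entry = sim.panel["ref01"]
reads = simulate_reads(
    sim.panel, ReadSimParams(n_reads=2_500, seq_error=0.005, seed=8),
    source_mix={"ref01": 1.0},
)
cfg = MapConfig()
alns, _ = map_reads(reads.reads, entry, cfg, SeedIndex(entry, cfg.k))
cons = call_consensus(dedup(filter_mapq(alns, cfg)), entry)
print(f"consensus: {cons.called_frac:.1%} of positions called "
      f"(uncalled positions have depth < 3 or an ambiguous pileup)")

seqs = {"sample": cons.sequence}
seqs.update({e.ref_id: e.sequence for e in sim.panel})
msa = anchor_msa(seqs, entry)
clean = strip_columns(msa, remove_cr=True, cr_interval=entry.cr_interval)
print(f"alignment: {msa.n_columns} -> {clean.n_columns} columns after removing "
      "the control region and all gap/N columns")

sites = classify_sites(clean)
print(f"variable sites: {sites.n_variable}, "
      f"parsimony-informative: {sites.n_parsimony_informative}")

groups = {sid: "canid" for sid in clean.seq_ids}
table = pairwise_diffs(clean, groups)
row = table.group_stats.iloc[0]
print(f"within-group pairwise differences: {row['mean']:.0f} ± {row['sd']:.0f} "
      f"over {int(row['n_pairs'])} pairs")
print(f"sample vs its source reference: "
      f"{sequence_identity(cons.sequence, entry.sequence):.2f}% identical — "
      "the consensus reproduces its source almost perfectly.")
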