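"""The core question: which reference panel member did a sample come from?

Simulates a read set from a dhole-like reference, maps it independently
against every panel member with the standard filters (length ≥ 30,
MAPQ ≥ 30, duplicates removed), and combines normalized read counts
with coverage evenness into a species call.
"""

from paleomito import (
    MapConfig,
    PanelSpec,
    ReadSimParams,
    SeedIndex,
    call_species,
    coverage_summary,
    dedup,
    filter_mapq,
    generate_panel,
    map_reads,
    normalized_counts,
    simulate_reads,
)

sim = generate_panel(PanelSpec(
    n_refs=5, ref_length=16_500, pairwise_divergence=0.08, seed=3,
    ref_ids=["dhole", "wolf", "coyote", "jackal", "human"],
    roles={"human": "contaminant_control"},
    branch_overrides={"human": 0.30},
))
reads = simulate_reads(
    sim.panel, ReadSimParams(n_reads=5_000, d5=0.2, d3=0.2, seq_error=0.005, seed=4),
    source_mix={"dhole": 1.0},
)

cfg = MapConfig()
summaries = []
for entry in sim.panel:
    alns, _ = map_reads(reads.reads, entry, cfg, SeedIndex(entry, cfg.k))
    kept = dedup(filter_mapq(alns, cfg))
    summaries.append(coverage_summary(kept, entry))

pct = normalized_counts(summaries)
print(f"{'reference':<10}{'mapped':>8}{'norm %':>9}{'evenness':>10}")
for s in summaries:
    print(f"{s.ref_id:<10}{s.n_mapped:>8}{pct[s.ref_id]:>9.1f}{s.evenness:>10.4f}")

call = call_species("sample1", summaries, sim.panel)
print(f"\nverdict: {call.verdict}")
print("Both lines of evidence point the same way: the true source attracts "
      "the most reads (100%) and covers its reference most evenly "
      "(evenness ≈ 1 means every position is touched at least once); "
      "~8%-divergent references lose both reads and breadth.")
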