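"""Authenticate a read set by its deamination signature.

Maps simulated reads carrying terminal damage back to their source and
profiles C→T (5' end) and G→A (3' end) mismatch frequencies by distance
from the read terminus, then fits the geometric decay model to recover
the damage parameters.
"""

from paleomito import (
    MapConfig,
    PanelSpec,
    ReadSimParams,
    SeedIndex,
    damage_profile,
    fit_damage_model,
    generate_panel,
    length_summary,
    map_reads,
    simulate_reads,
)

sim = generate_panel(PanelSpec(n_refs=2, ref_length=3_000, pairwise_divergence=0.08, seed=5))
entry = sim.panel["ref01"]
reads = simulate_reads(
    sim.panel,
    ReadSimParams(n_reads=20_000, d5=0.3, d3=0.3, decay_r=0.5, seq_error=0.005,
                  dup_rate=0.0, seed=6),
    source_mix={"ref01": 1.0},
)
cfg = MapConfig()
alns, _ = map_reads(reads.reads, entry, cfg, SeedIndex(entry, cfg.k))

prof = damage_profile(alns, entry)
print("offset   C>T @5'   G>A @3'")
for i in range(5):
    print(f"{i:>6}   {prof.pos5[i]:.4f}    {prof.pos3[i]:.4f}")

d5_hat, r_hat = fit_damage_model(prof)
print(f"\nfitted damage model: d5 = {d5_hat:.3f} (true 0.30), "
      f"decay r = {r_hat:.3f} (true 0.50)")

s = length_summary(alns)
print(f"fragment lengths: mean {s.mean:.1f} ± {s.sd:.1f} bp over {s.n} reads")
print("Elevated terminal substitution frequencies decaying into the read, "
      "plus short fragments, are the classic marks of authentic ancient DNA.")
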