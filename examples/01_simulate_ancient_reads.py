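"""Generate a synthetic reference panel and an ancient-style read set.

Builds four mitogenome-scale references at ~8% pairwise divergence
(roughly the dhole-wolf distance), draws 2,000 damaged single-end reads
from the first one, and prints the damage signal present in the raw
reads. Every read name encodes its true origin.
"""

from paleomito import PanelSpec, ReadSimParams, generate_panel, parse_read_id, simulate_reads

sim = generate_panel(PanelSpec(n_refs=4, ref_length=16_500,
                               pairwise_divergence=0.08, seed=1))
print("panel:", ", ".join(f"{e.ref_id} ({e.length} bp)" for e in sim.panel))
print(f"realized ref01-ref02 divergence: {sim.realized_divergence('ref01', 'ref02'):.4f}")

reads = simulate_reads(
    sim.panel,
    ReadSimParams(n_reads=2_000, d5=0.3, d3=0.3, decay_r=0.5, seq_error=0.005, seed=2),
    source_mix={"ref01": 1.0},
)
lens = reads.truth["length"]
print(f"\n{len(reads)} reads, lengths {lens.min()}-{lens.max()} "
      f"(mean {lens.mean():.1f}) — short right-skewed fragments, as in degraded DNA")

tag = parse_read_id(reads.reads[0][0])
print(f"first read's truth tag: source={tag.source_ref} start={tag.start} strand={tag.strand}")

# terminal C→T frequency straight from the generator's damage log
ct5 = reads.damage_log[reads.damage_log["kind"] == "CT"]
by_offset = ct5["offset5"].value_counts().sort_index()
print("\ndeamination events by 5' offset (geometric decay d5 * r^i):")
print(by_offset.head(4).to_string())
print("— the count roughly halves per position (r = 0.5), the signature "
      "used to authenticate ancient libraries.")
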