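"""Shared fixtures: small synthetic panels and mapped read sets.

Heavier simulations (the 20k-read damage set) are session-scoped so the
unit suite and the acceptance checks share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from paleomito import MapConfig, SeedIndex, filter_mapq, map_reads
from paleomito.simulate import PanelSpec, ReadSimParams, generate_panel, simulate_reads


@pytest.fixture(scope="session")
def small_panel():
    """Two 3 kb references at ~8% pairwise divergence, with mutation log."""
    return generate_panel(
        PanelSpec(n_refs=2, ref_length=3_000, pairwise_divergence=0.08, seed=11)
    )


@pytest.fixture(scope="session")
def canid_panel():
    """Four mitogenome-scale targets at ~8% divergence plus an outgroup
    and a distant contaminant-control reference."""
    return generate_panel(
        PanelSpec(
            n_refs=6,
            ref_length=16_500,
            pairwise_divergence=0.08,
            seed=7,
            ref_ids=["dhole", "wolf", "coyote", "jackal", "grayfox", "human"],
            roles={"grayfox": "outgroup", "human": "contaminant_control"},
            branch_overrides={"grayfox": 0.10, "human": 0.30},
        )
    )


@pytest.fixture(scope="session")
def damage_sim(small_panel):
    """20k reads at d5=0.3, decay_r=0.5 mapped back to their source."""
    params = ReadSimParams(
        n_reads=20_000, d5=0.3, d3=0.3, decay_r=0.5, seq_error=0.005,
        dup_rate=0.0, seed=23,
    )
    reads = simulate_reads(small_panel.panel, params, {"ref01": 1.0})
    entry = small_panel.panel["ref01"]
    cfg = MapConfig()
    alns, _ = map_reads(reads.reads, entry, cfg, SeedIndex(entry, cfg.k))
    kept = filter_mapq(alns, cfg)
    return {"panel": small_panel, "params": params, "reads": reads,
            "entry": entry, "alignments": kept}


def random_alignments(rng: np.random.Generator, entry, n: int):
    """Random AlignedRead sets on one reference, for coverage oracles."""
    from paleomito.mapping import AlignedRead

    L = entry.length
    out = []
    for i in range(n):
        start = int(rng.integers(0, L))
        length = int(rng.integers(30, 76))
        out.append(
            AlignedRead(
                read_id=f"r{i}",
                ref_id=entry.ref_id,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                n_mismatch=0,
                mapq=60,
                seq="A" * length,
            )
        )
    return out
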