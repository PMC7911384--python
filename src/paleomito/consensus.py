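"""Reference-coordinate consensus calling from read pileups.

A base is called at a reference position only when at least
``min_depth`` reads cover it (default 3) and the plurality base reaches
the consensus threshold (default 50 % of the pileup, inclusive).
Everything else — low depth, sub-threshold plurality, or a tie at the
top — is emitted as N, the conservative choice. Insertions relative to
the reference are not represented (reference-coordinate consensus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._dna import decode, encode
from .mapping import AlignedRead
from .panel import PanelEntry

__all__ = ["ConsensusSequence", "call_consensus"]


@dataclass
class ConsensusSequence:
    ref_id: str
    sequence: str  # per-position calls over {A,C,G,T,N}, length == reference length
    depth: np.ndarray = field(repr=False)

    @property
    def called_frac(self) -> float:
        if not self.sequence:
            return 0.0
        return 1.0 - self.sequence.count("N") / len(self.sequence)

    def write_fasta(self, path: str | Path, name: str | None = None) -> None:
        name = name or f"consensus_{self.ref_id}"
        with open(path, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    def write_tsv(self, path: str | Path) -> None:
        """Per-position table: pos (1-based), depth, call."""
        with open(path, "w") as fh:
            fh.write("pos\tdepth\tcall\n")
            for i, (d, c) in enumerate(zip(self.depth, self.sequence), start=1):
                fh.write(f"{i}\t{d}\t{c}\n")


def call_consensus(
    alignments: list[AlignedRead],
    entry: PanelEntry,
    min_depth: int = 3,
    threshold: float = 0.5,
    trim_terminal: int = 0,
) -> ConsensusSequence:
    """Call a consensus sequence from filtered, deduplicated alignments.

    ``trim_terminal`` excludes that many bases from each end of every
    read before piling up — a damage-aware mode that avoids terminal
    deamination miscalls on libraries without UDG treatment.
    """
    L = entry.length
    counts = np.zeros((4, L), dtype=np.int64)
    for a in alignments:
        codes = encode(a.seq)
        n = codes.size
        lo, hi = trim_terminal, n - trim_terminal
        if hi <= lo:
            continue
        pos = (a.start + np.arange(lo, hi)) % L
        sub = codes[lo:hi]
        keep = sub < 4
        np.add.at(counts, (sub[keep], pos[keep]), 1)

    depth = counts.sum(axis=0)
    part = np.sort(counts, axis=0)
    top, second = part[3], part[2]
    arg = counts.argmax(axis=0).astype(np.uint8)
    callable_ = (depth >= min_depth) & (top > second) & (top >= threshold * depth)
    calls = np.where(callable_, arg, np.uint8(4))
    return ConsensusSequence(ref_id=entry.ref_id, sequence=decode(calls), depth=depth)
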