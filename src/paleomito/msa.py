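"""Reference-anchored multiple alignment and diversity statistics.

Sequences (consensus calls, published mitogenomes) are each globally
aligned to a single anchor reference and stacked on the anchor's
coordinates; insertions relative to the anchor are dropped. For the
≥90 %-identical mitogenomes this package targets, the stacked alignment
is, after the downstream removal of every column containing a gap or an
uncalled base, essentially the alignment a progressive MSA would give —
while remaining exactly reproducible. Externally produced alignments
(aligned FASTA) can be imported to bypass the anchoring step entirely.

Column filtering removes the control region (by anchor annotation) and
every column containing '-' or 'N', restricting all downstream
statistics (variable / parsimony-informative sites, pairwise
differences, distances) to positions confidently covered by every
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

from ._dna import _CODE
from .panel import PanelEntry

__all__ = [
    "Msa",
    "SiteClassification",
    "PairwiseDiffTable",
    "anchor_msa",
    "strip_columns",
    "classify_sites",
    "pairwise_diffs",
    "sequence_identity",
    "read_aligned_fasta",
    "write_nexus",
]

GAP = np.uint8(5)  # codes 0-3 bases, 4 = N, 5 = '-'
_CHARS = np.frombuffer(b"ACGTN-", dtype=np.uint8)

# reject alignments near saturation: more than this fraction of edits
MAX_EDIT_FRAC = 0.45


def _make_aligner() -> Align.PairwiseAligner:
    # affine scoring keeps runs of substitutions from being absorbed into
    # spurious indel pairs, which a unit-cost aligner would happily do
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _encode_row(seq: str) -> np.ndarray:
    out = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)].copy()
    out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord("-")] = GAP
    return out


@dataclass
class Msa:
    """A rectangular alignment over {A,C,G,T,N,-} with anchor coordinates.

    ``column_map[j]`` is the 1-based anchor position of column ``j``,
    preserved through column filtering so intervals annotated on the
    anchor (e.g. the control region) stay addressable.
    """

    seq_ids: list[str]
    matrix: np.ndarray = field(repr=False)  # uint8, rows x columns
    column_map: np.ndarray = field(repr=False, default=None)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise ValueError("duplicate sequence ids in alignment")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.seq_ids):
            raise ValueError("matrix shape does not match seq_ids")
        if self.column_map is None:
            self.column_map = np.arange(1, self.matrix.shape[1] + 1)

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, seq_id: str) -> str:
        i = self.seq_ids.index(seq_id)
        return _CHARS[self.matrix[i]].tobytes().decode()

    def rows(self) -> dict[str, str]:
        return {sid: self.row(sid) for sid in self.seq_ids}

    def is_clean(self) -> bool:
        """True when no column contains a gap or an N."""
        return bool(np.all(self.matrix < 4))

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in self.seq_ids:
                fh.write(f">{sid}\n{self.row(sid)}\n")


def read_aligned_fasta(path: str | Path) -> Msa:
    """Import an externally produced alignment (aligned FASTA)."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_encode_row(str(rec.seq)))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    lens = {r.size for r in rows}
    if len(lens) != 1:
        raise ValueError("aligned FASTA rows have unequal lengths")
    return Msa(seq_ids=ids, matrix=np.vstack(rows))


def _global_alignment(query: str, target: str) -> tuple[list[tuple[int, str]], int, int]:
    """Affine-scored global alignment of query against target.

    Returns (ops, n_match, n_mismatch) where ops is a run-length list
    over {'M' both advance, 'D' target-only (gap in query), 'I'
    query-only (insertion relative to target)}. Columns where either
    base is N are excluded from the match/mismatch tallies. Alignments
    whose edit fraction (mismatches + gap columns over all columns)
    exceeds the sanity floor are rejected as unalignable.
    """
    q, t = query.upper(), target.upper()
    aln = _ALIGNER.align(t, q)[0]
    coords = np.asarray(aln.coordinates)
    qe = _CODE[np.frombuffer(q.encode(), dtype=np.uint8)]
    te = _CODE[np.frombuffer(t.encode(), dtype=np.uint8)]
    ops: list[tuple[int, str]] = []
    n_match = n_mismatch = n_gap = 0
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        dt, dq = t1 - t0, q1 - q0
        if dt and dq:
            ops.append((dt, "M"))
            tb, qb = te[t0:t1], qe[q0:q1]
            valid = (tb < 4) & (qb < 4)
            eq = int(((tb == qb) & valid).sum())
            n_match += eq
            n_mismatch += int(valid.sum()) - eq
        elif dt:
            ops.append((dt, "D"))
            n_gap += dt
        elif dq:
            ops.append((dq, "I"))
            n_gap += dq
    total = n_match + n_mismatch + n_gap
    if total == 0 or (n_mismatch + n_gap) > MAX_EDIT_FRAC * total:
        raise ValueError(
            f"unalignable sequence: {n_mismatch} mismatches and {n_gap} gap "
            f"columns over {total} comparable columns"
        )
    return ops, n_match, n_mismatch


def anchor_msa(sequences: dict[str, str], anchor: PanelEntry) -> Msa:
    """Stack sequences on the anchor's coordinates by global alignment.

    Each sequence is aligned to the anchor end-to-end; columns are the
    anchor's positions, deletions relative to the anchor appear as '-',
    and insertions relative to the anchor are dropped (they would be
    removed as gap columns downstream regardless). Sequences whose edit
    fraction exceeds the sanity floor are rejected as unalignable.
    """
    L = anchor.length
    ids, rows = [], []
    for sid, seq in sequences.items():
        ops, _, _ = _global_alignment(seq, anchor.sequence)
        row = np.full(L, GAP, dtype=np.uint8)
        qcodes = _encode_row(seq)
        qi = ti = 0
        for n, op in ops:
            if op == "M":
                row[ti : ti + n] = qcodes[qi : qi + n]
                qi += n
                ti += n
            elif op == "D":  # gap in query: anchor positions uncovered
                ti += n
            else:  # 'I': insertion relative to the anchor, dropped
                qi += n
        ids.append(sid)
        rows.append(row)
    return Msa(seq_ids=ids, matrix=np.vstack(rows), column_map=np.arange(1, L + 1))


def strip_columns(
    msa: Msa,
    remove_cr: bool = False,
    cr_interval: tuple[int, int] | None = None,
) -> Msa:
    """Keep only columns with no gap and no N, optionally excising the
    control region (1-based inclusive interval on anchor coordinates)."""
    keep = np.all(msa.matrix < 4, axis=0)
    if remove_cr:
        if cr_interval is None:
            raise ValueError("remove_cr requires a control-region interval")
        a, b = cr_interval
        keep &= ~((msa.column_map >= a) & (msa.column_map <= b))
    out = Msa(
        seq_ids=list(msa.seq_ids),
        matrix=msa.matrix[:, keep],
        column_map=msa.column_map[keep],
    )
    if out.n_columns == 0:
        out.flags.append("all_columns_removed")
    return out


@dataclass
class SiteClassification:
    n_columns: int
    n_variable: int
    n_parsimony_informative: int


def classify_sites(msa: Msa) -> SiteClassification:
    """Count variable and parsimony-informative columns.

    A column is variable with ≥2 distinct states; parsimony-informative
    with ≥2 states each present in ≥2 sequences. Requires a gap/N-free
    alignment.
    """
    if msa.n_columns == 0:
        raise ValueError("empty alignment")
    if not msa.is_clean():
        raise ValueError("site classification requires a gap/N-free alignment")
    counts = np.stack([(msa.matrix == s).sum(axis=0) for s in range(4)])
    n_states = (counts > 0).sum(axis=0)
    n_repeated = (counts >= 2).sum(axis=0)
    return SiteClassification(
        n_columns=msa.n_columns,
        n_variable=int((n_states >= 2).sum()),
        n_parsimony_informative=int((n_repeated >= 2).sum()),
    )


@dataclass
class PairwiseDiffTable:
    """Absolute pairwise difference counts with within-group summaries."""

    seq_ids: list[str]
    labels: dict[str, str]
    counts: pd.DataFrame  # symmetric, zero diagonal
    group_stats: pd.DataFrame  # group, n_seqs, n_pairs, mean, sd
    flags: list[str]


def pairwise_diffs(msa: Msa, groups: dict[str, str] | None = None) -> PairwiseDiffTable:
    """Hamming distances between all rows, summarised within groups.

    Within-group mean and (sample) standard deviation are reported for
    groups with at least two members; smaller groups are flagged.
    """
    if not msa.is_clean():
        raise ValueError("pairwise differences require a gap/N-free alignment")
    groups = groups or {sid: "all" for sid in msa.seq_ids}
    m = msa.matrix
    diffs = (m[:, None, :] != m[None, :, :]).sum(axis=2)
    counts = pd.DataFrame(diffs, index=msa.seq_ids, columns=msa.seq_ids)

    flags: list[str] = []
    rows = []
    for g in sorted(set(groups.values())):
        members = [s for s in msa.seq_ids if groups.get(s) == g]
        if len(members) < 2:
            flags.append(f"group {g!r} has fewer than 2 members; no within-group stats")
            continue
        vals = []
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                vals.append(counts.loc[a, b])
        vals = np.array(vals, dtype=float)
        rows.append(
            (g, len(members), vals.size, float(vals.mean()),
             float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        )
    stats = pd.DataFrame(rows, columns=["group", "n_seqs", "n_pairs", "mean", "sd"])
    return PairwiseDiffTable(
        seq_ids=list(msa.seq_ids), labels=dict(groups), counts=counts,
        group_stats=stats, flags=flags,
    )


def sequence_identity(a: str, b: str) -> float:
    """Percent identity over a pairwise global alignment.

    Matches divided by aligned columns, excluding columns where either
    sequence has a gap or an uncalled base (N).
    """
    _, n_match, n_mismatch = _global_alignment(a, b)
    if n_match + n_mismatch == 0:
        raise ValueError("no gap-free columns in the pairwise alignment")
    return 100.0 * n_match / (n_match + n_mismatch)


def write_nexus(msa: Msa, path: str | Path) -> None:
    """Export as a minimal NEXUS DATA block (popart-compatible)."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={msa.n_seqs} NCHAR={msa.n_columns};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
        width = max(len(s) for s in msa.seq_ids) + 2
        for sid in msa.seq_ids:
            safe = sid.replace(" ", "_")
            fh.write(f"    {safe:<{width}}{msa.row(sid)}\n")
        fh.write("  ;\nEND;\n")
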