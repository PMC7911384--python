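"""Desk-scale ungapped read mapping against circular references.

Each reference is indexed with its k-mers; reads are placed by seeding
(non-overlapping k-mer seeds, so any placement with fewer mismatches
than seeds is guaranteed to be found) and scored by exact mismatch
counting over both strands. Circularity is handled by indexing the
sequence doubled by ``max_read_len - 1`` bases, so origin-spanning
placements are ordinary slices; reported starts are always in
``[0, L)`` and ``end`` may exceed ``L`` before the modular wrap.

The mapping-quality proxy reflects placement uniqueness: 60 when the
second-best placement has at least 3 more mismatches than the best,
``25 * margin`` for margins of 1–2, and 0 on ties — filtered downstream
at ``mapq >= 30`` like the study's MAPQ filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from ._dna import encode, revcomp, revcomp_codes
from .panel import PanelEntry

__all__ = [
    "MapConfig",
    "AlignedRead",
    "SeedIndex",
    "map_read",
    "map_reads",
    "dedup",
    "filter_mapq",
    "write_sam",
    "read_sam",
]


@dataclass
class MapConfig:
    """Mapping thresholds.

    The default seed length 7 keeps ``floor(min_read_len / k)`` disjoint
    seeds above the mismatch budget ``floor(max_mismatch_frac * len)``
    for every legal read length, so any placement within the budget is
    guaranteed to share at least one exact seed with the reference.
    """

    k: int = 7
    max_mismatch_frac: float = 0.1
    mapq_min: int = 30
    min_read_len: int = 30
    max_read_len: int = 75

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.min_read_len):
            raise ValueError("need 1 <= k <= min_read_len")
        if not (0.0 <= self.max_mismatch_frac <= 0.5):
            raise ValueError("max_mismatch_frac must lie in [0, 0.5]")


@dataclass
class AlignedRead:
    """One read's placement on one reference.

    ``start`` is 0-based on the linearized reference; ``end`` is
    exclusive and may exceed the reference length for origin-spanning
    placements. ``seq`` is the read sequence oriented along the forward
    reference strand, so reference position ``(start + i) % L`` is
    covered by ``seq[i]``.
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    n_mismatch: int
    mapq: int
    seq: str

    @property
    def aligned_len(self) -> int:
        return self.end - self.start

    def read_sequence(self) -> str:
        """The read as sequenced (5'→3' in read orientation)."""
        return self.seq if self.strand == "+" else revcomp(self.seq)


class SeedIndex:
    """Exact k-mer index over a (possibly doubled) reference sequence."""

    def __init__(self, entry: PanelEntry, k: int, max_read_len: int = 75):
        if k > entry.length:
            raise ValueError(f"k={k} exceeds reference length {entry.length}")
        self.entry = entry
        self.k = k
        self.L = entry.length
        codes = encode(entry.sequence)
        if entry.circular:
            ext = np.concatenate([codes, codes[: max_read_len - 1]])
        else:
            ext = codes
        self.ext = ext
        npos = ext.size - k + 1
        if npos <= 0:
            raise ValueError("reference shorter than k")
        win = np.lib.stride_tricks.sliding_window_view(ext, k)
        powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        ids = win.astype(np.int64) @ powers
        # k-mers containing N are unindexable
        has_n = np.convolve((ext == 4).astype(np.int64), np.ones(k, dtype=np.int64))[
            k - 1 : k - 1 + npos
        ]
        ids[has_n > 0] = -1
        order = np.argsort(ids, kind="stable")
        self._sorted_ids = ids[order]
        self._sorted_pos = order.astype(np.int64)
        self._powers = powers

    def kmer_id(self, codes: np.ndarray) -> int:
        if np.any(codes == 4):
            return -1
        return int(codes.astype(np.int64) @ self._powers)

    def lookup(self, kmer_id: int) -> np.ndarray:
        """Start positions (on the doubled sequence) of an exact k-mer."""
        if kmer_id < 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._sorted_ids, kmer_id, side="left")
        hi = np.searchsorted(self._sorted_ids, kmer_id, side="right")
        return self._sorted_pos[lo:hi]

    def lookup_kmer(self, kmer: str) -> np.ndarray:
        """Positions of a k-mer given as a string, mapped into [0, L)."""
        pos = self.lookup(self.kmer_id(encode(kmer)))
        return np.unique(pos % self.L) if self.entry.circular else np.sort(pos)


def _candidates(index: SeedIndex, codes: np.ndarray, k: int) -> np.ndarray:
    """Candidate 0-based start positions sharing at least one exact seed."""
    n = codes.size
    offsets = list(range(0, n - k + 1, k))
    if offsets[-1] != n - k:
        offsets.append(n - k)
    cands: list[np.ndarray] = []
    for off in offsets:
        hits = index.lookup(index.kmer_id(codes[off : off + k]))
        if hits.size:
            cands.append(hits - off)
    if not cands:
        return np.empty(0, dtype=np.int64)
    starts = np.unique(np.concatenate(cands))
    starts = starts[(starts >= 0) & (starts < index.L)]
    if not index.entry.circular:
        starts = starts[starts + n <= index.L]
    return starts


def _mismatch_counts(index: SeedIndex, codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
    seg = index.ext[starts[:, None] + np.arange(codes.size)]
    return ((seg != codes) | (seg == 4) | (codes == 4)).sum(axis=1)


def map_read(
    read: str,
    entry: PanelEntry,
    cfg: MapConfig | None = None,
    index: SeedIndex | None = None,
    read_id: str = "read",
) -> AlignedRead | None:
    """Best ungapped placement of a read over both strands, or None.

    Placements are found by exact-seed candidates, guaranteeing the true
    best placement is recovered whenever its mismatch count is below the
    number of non-overlapping seeds. The placement is rejected if its
    mismatch fraction exceeds ``cfg.max_mismatch_frac``.
    """
    cfg = cfg or MapConfig()
    if len(read) < cfg.min_read_len:
        return None
    index = index or SeedIndex(entry, cfg.k, cfg.max_read_len)
    fwd = encode(read)
    rev = revcomp_codes(fwd)

    best: tuple[int, int, str] | None = None  # (mism, start, strand)
    second: int | None = None
    for strand, codes in (("+", fwd), ("-", rev)):
        starts = _candidates(index, codes, cfg.k)
        if not starts.size:
            continue
        mism = _mismatch_counts(index, codes, starts)
        for s, m in zip(starts.tolist(), mism.tolist()):
            key = (m, s, strand)
            if best is None or key < (best[0], best[1], best[2]):
                if best is not None:
                    cand_second = best[0]
                    second = cand_second if second is None else min(second, cand_second)
                best = key
            else:
                second = m if second is None else min(second, m)

    if best is None:
        return None
    n_mm, start, strand = best
    if n_mm > int(cfg.max_mismatch_frac * len(read)):
        return None
    if second is None:
        mapq = 60
    else:
        margin = second - n_mm
        mapq = 0 if margin <= 0 else min(25 * margin, 60) if margin < 3 else 60
    seq = read if strand == "+" else revcomp(read)
    return AlignedRead(
        read_id=read_id,
        ref_id=entry.ref_id,
        start=start,
        end=start + len(read),
        strand=strand,
        n_mismatch=n_mm,
        mapq=mapq,
        seq=seq,
    )


def map_reads(
    reads: list[tuple[str, str]],
    entry: PanelEntry,
    cfg: MapConfig | None = None,
    index: SeedIndex | None = None,
) -> tuple[list[AlignedRead], dict[str, str]]:
    """Map (read_id, sequence) pairs to one reference.

    Returns the alignments and a dict of unmapped read ids to a reason
    (``too_short`` or ``no_placement``).
    """
    cfg = cfg or MapConfig()
    index = index or SeedIndex(entry, cfg.k, cfg.max_read_len)
    alignments: list[AlignedRead] = []
    unmapped: dict[str, str] = {}
    for rid, seq in reads:
        if len(seq) < cfg.min_read_len:
            unmapped[rid] = "too_short"
            continue
        aln = map_read(seq, entry, cfg, index, read_id=rid)
        if aln is None:
            unmapped[rid] = "no_placement"
        else:
            alignments.append(aln)
    return alignments, unmapped


def dedup(alignments: list[AlignedRead]) -> list[AlignedRead]:
    """Collapse coordinate duplicates: one record per (start, end, strand).

    The retained record has the highest mapq; ties break to the
    lexicographically smallest read_id, so the result is deterministic
    and independent of input order.
    """
    refs = {a.ref_id for a in alignments}
    if len(refs) > 1:
        raise ValueError(f"dedup expects alignments on one reference, got {sorted(refs)}")
    best: dict[tuple[int, int, str], AlignedRead] = {}
    for a in alignments:
        key = (a.start, a.end, a.strand)
        cur = best.get(key)
        if cur is None or (-a.mapq, a.read_id) < (-cur.mapq, cur.read_id):
            best[key] = a
    return [best[k] for k in sorted(best)]


def filter_mapq(alignments: list[AlignedRead], cfg: MapConfig | None = None) -> list[AlignedRead]:
    """Retain alignments with mapq >= cfg.mapq_min (default 30)."""
    cfg = cfg or MapConfig()
    return [a for a in alignments if a.mapq >= cfg.mapq_min]


# --------------------------------------------------------------------------
# SAM I/O
# --------------------------------------------------------------------------

def write_sam(alignments: list[AlignedRead], entry: PanelEntry, path: str | Path) -> None:
    """Write alignments as plain-text SAM (POS 1-based, NM tag).

    Origin-spanning reads are written at their start position with a
    full-length match operation extending past the reference end — the
    documented convention for circular references.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{entry.ref_id}\tLN:{entry.length}\n")
        fh.write("@PG\tID:paleomito\tPN:paleomito\n")
        for a in sorted(alignments, key=lambda x: (x.start, x.end, x.read_id)):
            flag = 16 if a.strand == "-" else 0
            fh.write(
                f"{a.read_id}\t{flag}\t{entry.ref_id}\t{a.start + 1}\t{a.mapq}\t"
                f"{a.aligned_len}M\t*\t0\t0\t{a.seq}\t{'F' * len(a.seq)}\tNM:i:{a.n_mismatch}\n"
            )


def read_sam(path: str | Path, ref_id: str | None = None) -> list[AlignedRead]:
    """Ingest alignments from SAM produced by this package or any mapper.

    Soft/hard clips and indels are accepted; ``aligned_len`` then counts
    reference-consuming operations. Unmapped and secondary records are
    skipped.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if ref_id is not None and rec.reference_name != ref_id:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            ref_len = rec.reference_length or len(rec.query_sequence or "")
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_start + ref_len,
                    strand="-" if rec.is_reverse else "+",
                    n_mismatch=int(nm),
                    mapq=rec.mapping_quality,
                    seq=rec.query_sequence or "",
                )
            )
    return out
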