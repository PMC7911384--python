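"""Mapper correctness against brute-force alignment oracles, circular
placements, the mapping-quality proxy, and the duplicate/MAPQ filters."""

import numpy as np
import pytest

from paleomito import (
    AlignedRead,
    MapConfig,
    SeedIndex,
    dedup,
    filter_mapq,
    map_read,
    map_reads,
    read_sam,
    revcomp,
    write_sam,
)
from paleomito._dna import encode
from paleomito.panel import PanelEntry
from paleomito.simulate import ReadSimParams, simulate_reads


def _random_entry(rng, length, ref_id="r", circular=True):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return PanelEntry(ref_id=ref_id, sequence=seq, circular=circular)


def brute_force_best(read: str, entry: PanelEntry) -> tuple[int, int, str]:
    """Exhaustive all-positions/all-strands scan: (mismatches, start, strand)."""
    L = entry.length
    ext = encode(entry.sequence + entry.sequence[: len(read) - 1])
    best = None
    for strand, seq in (("+", read), ("-", revcomp(read))):
        codes = encode(seq)
        win = np.lib.stride_tricks.sliding_window_view(ext, len(read))[:L]
        mism = ((win != codes) | (win == 4) | (codes == 4)).sum(axis=1)
        for start in range(L):
            key = (int(mism[start]), start, strand)
            if best is None or key < best:
                best = key
    return best


class TestSeedIndex:
    def test_hand_enumerable_circular_kmers(self):
        entry = PanelEntry(ref_id="x", sequence="ACGTACGT", circular=True)
        idx = SeedIndex(entry, k=4, max_read_len=8)
        assert set(idx.lookup_kmer("TACG")) == {3, 7}

    def test_k_equals_length(self):
        entry = PanelEntry(ref_id="x", sequence="ACGTAA", circular=False)
        idx = SeedIndex(entry, k=6, max_read_len=6)
        assert list(idx.lookup_kmer("ACGTAA")) == [0]
        assert idx.lookup_kmer("AAAAAA").size == 0

    def test_lookups_agree_with_substring_scan(self):
        rng = np.random.default_rng(1)
        entry = _random_entry(rng, 2_000)
        k = 8
        idx = SeedIndex(entry, k=k, max_read_len=40)
        doubled = entry.sequence + entry.sequence[:39]
        for _ in range(100):
            pos = int(rng.integers(0, 2_000))
            kmer = doubled[pos : pos + k]
            expect = sorted(
                {i % 2_000 for i in range(len(doubled) - k + 1) if doubled[i : i + k] == kmer}
            )
            assert list(idx.lookup_kmer(kmer)) == expect


class TestMapRead:
    def test_planted_exact_match(self):
        rng = np.random.default_rng(2)
        entry = _random_entry(rng, 16_000)
        read = entry.sequence[100:140]
        aln = map_read(read, entry)
        assert (aln.start, aln.strand, aln.n_mismatch, aln.mapq) == (100, "+", 0, 60)

    def test_circular_junction_read(self):
        rng = np.random.default_rng(3)
        entry = _random_entry(rng, 1_000)
        read = entry.sequence[990:] + entry.sequence[:20]
        aln = map_read(read, entry)
        assert (aln.start, aln.end) == (990, 1_020)

    def test_reverse_complement_maps_mirrored(self):
        rng = np.random.default_rng(4)
        entry = _random_entry(rng, 4_000)
        read = entry.sequence[500:550]
        fwd = map_read(read, entry)
        rev = map_read(revcomp(read), entry)
        assert (fwd.start, fwd.end) == (rev.start, rev.end)
        assert {fwd.strand, rev.strand} == {"+", "-"}
        assert fwd.seq == rev.seq  # stored in reference orientation

    def test_placements_match_brute_force_scan(self):
        """Reads with up to 3 planted mismatches place exactly where the
        exhaustive all-positions/all-strands oracle says."""
        rng = np.random.default_rng(5)
        entry = _random_entry(rng, 4_000)
        cfg = MapConfig()
        for i in range(1_000):
            n = int(rng.integers(35, 71))
            start = int(rng.integers(0, 4_000))
            frag = list((entry.sequence * 2)[start : start + n])
            n_mm = int(rng.integers(0, 4))
            for p in rng.choice(n, size=n_mm, replace=False):
                frag[p] = "ACGT"[("ACGT".index(frag[p]) + 1 + int(rng.integers(3))) % 4]
            read = "".join(frag)
            if rng.random() < 0.5:
                read = revcomp(read)
            aln = map_read(read, entry, cfg)
            mism, bstart, bstrand = brute_force_best(read, entry)
            assert aln is not None
            assert (aln.n_mismatch, aln.start, aln.strand) == (mism, bstart, bstrand)

    def test_repeat_region_read_gets_mapq_zero(self):
        rng = np.random.default_rng(6)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40))
        filler = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
        entry = PanelEntry(ref_id="rep", sequence=core + filler + core, circular=False)
        aln = map_read(core, entry)
        assert aln.mapq == 0
        assert filter_mapq([aln]) == []

    def test_short_read_filtered_with_reason(self):
        rng = np.random.default_rng(7)
        entry = _random_entry(rng, 500)
        alns, unmapped = map_reads([("tiny", "ACGTACGT")], entry)
        assert alns == [] and unmapped == {"tiny": "too_short"}

    def test_simulated_reads_map_back_to_truth(self, canid_panel):
        """≥99% of clean (damage/error-free) reads recover their coordinates."""
        params = ReadSimParams(n_reads=5_000, d5=0, d3=0, seq_error=0.0,
                               dup_rate=0.0, seed=12)
        out = simulate_reads(canid_panel.panel, params, {"dhole": 1.0})
        entry = canid_panel.panel["dhole"]
        cfg = MapConfig()
        idx = SeedIndex(entry, cfg.k)
        ok = 0
        for (rid, seq), row in zip(out.reads, out.truth.itertuples()):
            aln = map_read(seq, entry, cfg, idx, read_id=rid)
            if aln and aln.start == row.start and aln.strand == row.strand:
                ok += 1
        assert ok / len(out.reads) >= 0.99


def _mk(start, end, strand, mapq=60, rid="r", ref="x"):
    return AlignedRead(read_id=rid, ref_id=ref, start=start, end=end,
                       strand=strand, n_mismatch=0, mapq=mapq, seq="A" * (end - start))


class TestDedup:
    def test_coordinate_duplicates_collapse(self):
        out = dedup([_mk(10, 50, "+", rid="a"), _mk(10, 50, "+", rid="b")])
        assert len(out) == 1

    def test_different_ends_both_survive(self):
        out = dedup([_mk(10, 50, "+"), _mk(10, 60, "+")])
        assert len(out) == 2

    def test_retention_rule_and_oracle(self):
        rng = np.random.default_rng(8)
        alns = [
            _mk(int(rng.integers(0, 5)), int(rng.integers(50, 53)),
                "+-"[int(rng.integers(2))], mapq=int(rng.integers(0, 61)),
                rid=f"r{rng.integers(0, 100):03d}")
            for _ in range(500)
        ]
        out = dedup(alns)
        # oracle: group by coordinate key, keep (max mapq, min read_id)
        groups = {}
        for a in alns:
            groups.setdefault((a.start, a.end, a.strand), []).append(a)
        expect = {
            k: min(v, key=lambda a: (-a.mapq, a.read_id)) for k, v in groups.items()
        }
        assert {(a.start, a.end, a.strand): (a.mapq, a.read_id) for a in out} == {
            k: (a.mapq, a.read_id) for k, a in expect.items()
        }
        assert dedup(out) == out  # idempotent

    def test_mixed_references_rejected(self):
        with pytest.raises(ValueError):
            dedup([_mk(0, 10, "+", ref="x"), _mk(0, 10, "+", ref="y")])


class TestFilterMapq:
    @pytest.mark.parametrize("mapq,kept", [(29, False), (30, True)])
    def test_threshold_boundary(self, mapq, kept):
        out = filter_mapq([_mk(0, 40, "+", mapq=mapq)])
        assert bool(out) is kept

    def test_empty_input(self):
        assert filter_mapq([]) == []


class TestSamIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        entry = _random_entry(rng, 1_000)
        reads = [(f"q{i}", (entry.sequence * 2)[s : s + 40])
                 for i, s in enumerate(rng.integers(0, 1_000, size=20).tolist())]
        alns, _ = map_reads(reads, entry)
        path = tmp_path / "out.sam"
        write_sam(alns, entry, path)
        back = read_sam(path)
        key = lambda a: (a.read_id, a.start, a.end, a.strand, a.n_mismatch, a.mapq)
        assert sorted(map(key, back)) == sorted(map(key, alns))
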