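"""Anchored alignment, column filtering, site classification, pairwise
differences and percent identity, checked against per-column oracles and
the panel generator's mutation log."""

import numpy as np
import pytest

from paleomito import (
    Msa,
    anchor_msa,
    classify_sites,
    pairwise_diffs,
    read_aligned_fasta,
    sequence_identity,
    strip_columns,
    write_nexus,
)
from paleomito.haplonet import read_nexus_alignment
from paleomito.simulate import PanelSpec, generate_panel


def _msa(rows: dict[str, str]) -> Msa:
    from paleomito.msa import _encode_row

    return Msa(seq_ids=list(rows), matrix=np.vstack([_encode_row(s) for s in rows.values()]))


@pytest.fixture(scope="module")
def star_panel():
    return generate_panel(
        PanelSpec(n_refs=5, ref_length=4_000, pairwise_divergence=0.05, seed=17)
    )


class TestAnchorMsa:
    def test_identical_sequences_stack_without_gaps(self, star_panel):
        anchor = star_panel.panel["ref01"]
        m = anchor_msa({"a": anchor.sequence, "b": anchor.sequence}, anchor)
        assert m.row("a") == anchor.sequence and m.row("b") == anchor.sequence

    def test_deletion_becomes_gaps_at_anchor_positions(self, star_panel):
        anchor = star_panel.panel["ref01"]
        seq = anchor.sequence[:100] + anchor.sequence[103:]
        m = anchor_msa({"del3": seq}, anchor)
        row = m.row("del3")
        assert row.count("-") == 3
        # the gap run sits at the deleted anchor coordinates (alignment may
        # slide within a repeat, but stays in the immediate neighbourhood)
        gap_pos = [i for i, c in enumerate(row) if c == "-"]
        assert all(95 <= p <= 108 for p in gap_pos)

    def test_insertion_relative_to_anchor_is_dropped(self, star_panel):
        anchor = star_panel.panel["ref01"]
        seq = anchor.sequence[:200] + "ACGTA" + anchor.sequence[200:]
        m = anchor_msa({"ins": seq}, anchor)
        assert m.n_columns == anchor.length
        assert m.row("ins").count("-") == 0

    def test_divergent_panel_diffs_match_mutation_log(self, star_panel):
        """Pairwise differences read off the anchored MSA equal direct
        sequence comparison — the generator's substitution-only evolution
        guarantees shared coordinates."""
        anchor = star_panel.panel["ref01"]
        seqs = {e.ref_id: e.sequence for e in star_panel.panel}
        m = strip_columns(anchor_msa(seqs, anchor))
        table = pairwise_diffs(m)
        for a in star_panel.panel.ref_ids:
            for b in star_panel.panel.ref_ids:
                expected = sum(
                    1 for x, y in zip(seqs[a], seqs[b]) if x != y
                )
                assert table.counts.loc[a, b] == expected

    def test_garbage_sequence_rejected(self, star_panel):
        anchor = star_panel.panel["ref01"]
        rng = np.random.default_rng(1)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, size=4_000))
        with pytest.raises(ValueError, match="unalignable"):
            anchor_msa({"junk": junk}, anchor)


class TestStripColumns:
    def test_n_column_removed(self):
        m = _msa({"a": "ACGTACGTAC", "b": "ACGTACGNAC"})
        out = strip_columns(m)
        assert out.n_columns == 9 and 8 not in out.column_map.tolist()

    def test_noop_without_gaps(self):
        m = _msa({"a": "ACGT", "b": "ACGA"})
        out = strip_columns(m)
        assert out.n_columns == 4

    def test_idempotent(self):
        m = _msa({"a": "AC-TACGTAC", "b": "ACGTACGNAC"})
        once = strip_columns(m)
        twice = strip_columns(once)
        assert np.array_equal(once.matrix, twice.matrix)
        assert np.array_equal(once.column_map, twice.column_map)

    def test_control_region_excised_by_anchor_coordinate(self):
        m = _msa({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        out = strip_columns(m, remove_cr=True, cr_interval=(3, 5))
        assert out.n_columns == 7
        assert set(out.column_map.tolist()) == {1, 2, 6, 7, 8, 9, 10}

    def test_everything_removed_flagged(self):
        m = _msa({"a": "NNN", "b": "ACG"})
        out = strip_columns(m)
        assert out.n_columns == 0 and "all_columns_removed" in out.flags


class TestClassifySites:
    @pytest.mark.parametrize(
        "col,variable,informative",
        [("AAAA", 0, 0), ("AACC", 1, 1), ("AAAC", 1, 0), ("AACG", 1, 0)],
    )
    def test_hand_columns(self, col, variable, informative):
        m = _msa({f"s{i}": c for i, c in enumerate(col)})
        s = classify_sites(m)
        assert (s.n_variable, s.n_parsimony_informative) == (variable, informative)

    def test_matches_brute_force_tally_on_random_alignments(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            n, m = int(rng.integers(2, 9)), int(rng.integers(1, 40))
            mat = rng.integers(0, 4, size=(n, m)).astype(np.uint8)
            msa = Msa(seq_ids=[f"s{i}" for i in range(n)], matrix=mat)
            got = classify_sites(msa)
            nv = ni = 0
            for j in range(m):
                from collections import Counter

                c = Counter(mat[:, j].tolist())
                if len(c) >= 2:
                    nv += 1
                if sum(1 for v in c.values() if v >= 2) >= 2:
                    ni += 1
            assert (got.n_variable, got.n_parsimony_informative) == (nv, ni)

    def test_gapped_alignment_rejected(self):
        with pytest.raises(ValueError):
            classify_sites(_msa({"a": "A-G", "b": "ACG"}))


class TestPairwiseDiffs:
    def test_identical_and_simple_counts(self):
        t = pairwise_diffs(_msa({"a": "AAAA", "b": "AAAA", "c": "AATT"}))
        assert t.counts.loc["a", "b"] == 0 and t.counts.loc["a", "c"] == 2

    def test_row_order_invariance(self, star_panel):
        seqs = {e.ref_id: e.sequence for e in star_panel.panel}
        anchor = star_panel.panel["ref01"]
        m = strip_columns(anchor_msa(seqs, anchor))
        rev = Msa(seq_ids=list(reversed(m.seq_ids)), matrix=m.matrix[::-1].copy())
        t1, t2 = pairwise_diffs(m), pairwise_diffs(rev)
        for a in m.seq_ids:
            for b in m.seq_ids:
                assert t1.counts.loc[a, b] == t2.counts.loc[a, b]

    def test_star_tree_within_group_mean_near_2m(self):
        """On a star topology each pair differs at ~2m sites for per-branch
        mutation count m (minus rare coincident hits)."""
        sim = generate_panel(
            PanelSpec(n_refs=6, ref_length=8_000, pairwise_divergence=0.02, seed=3)
        )
        seqs = {e.ref_id: e.sequence for e in sim.panel}
        m = strip_columns(anchor_msa(seqs, sim.panel["ref01"]))
        t = pairwise_diffs(m, {sid: "grp" for sid in m.seq_ids})
        mean_branch = np.mean([len(v) for v in sim.variant_sites.values()])
        got = t.group_stats.set_index("group").loc["grp", "mean"]
        assert got == pytest.approx(2 * mean_branch, rel=0.1)

    def test_small_group_flagged(self):
        t = pairwise_diffs(_msa({"a": "AAAA", "b": "AATT"}), {"a": "g1", "b": "g2"})
        assert len(t.flags) == 2 and t.group_stats.empty


class TestSequenceIdentity:
    def test_identical_is_100(self):
        assert sequence_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_known_divergence_panel(self):
        sim = generate_panel(
            PanelSpec(n_refs=2, ref_length=16_000, pairwise_divergence=0.08, seed=4)
        )
        ident = sequence_identity(
            sim.panel["ref01"].sequence, sim.panel["ref02"].sequence
        )
        assert ident == pytest.approx(92.0, abs=1.0)
        # cross-check against the generator's mutation log
        assert ident == pytest.approx(100 * (1 - sim.realized_divergence("ref01", "ref02")),
                                      abs=1e-9)


class TestIO:
    def test_aligned_fasta_roundtrip(self, tmp_path):
        m = _msa({"a": "ACGTAC-TAC", "b": "ACNTACGTAC"})
        m.write_fasta(tmp_path / "m.fa")
        back = read_aligned_fasta(tmp_path / "m.fa")
        assert back.rows() == m.rows()

    def test_nexus_roundtrip(self, tmp_path):
        m = _msa({"a": "ACGTACGTAC", "b": "ACTTACGTAC"})
        write_nexus(m, tmp_path / "m.nex")
        back = read_nexus_alignment(tmp_path / "m.nex")
        assert back.rows() == m.rows()
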