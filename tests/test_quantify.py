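from dataclasses import replace

import numpy as np
import pytest

from mirexport import (
    Alignment,
    Hairpin,
    HairpinReference,
    MatureArm,
    Read,
    ReadSet,
    align_read,
    assign_to_mature,
    count_libraries,
)
from mirexport import trim_adapters
from mirexport.simulate import SimulationConfig, simulate_libraries, simulate_reference

from conftest import brute_force_align


def _trimmed(readsets, label):
    out, _ = trim_adapters(readsets[label])
    return out


def _mature_seq(ref, mature_id):
    for hp in ref:
        for arm in hp.matures:
            if arm.mature_id == mature_id:
                return hp, arm, hp.mature_sequence(arm)
    raise KeyError(mature_id)


class TestAlignRead:
    def test_mature_subsequence_aligns_at_annotated_start(self, toy_ref):
        hp, arm, seq = _mature_seq(toy_ref, "mir-a")
        hits = align_read(seq, toy_ref)
        assert len(hits) == 1
        aln = hits[0]
        assert (aln.hairpin_id, aln.start, aln.mismatches) == (hp.hairpin_id, arm.start, 0)

    def test_three_substitutions_everywhere_returns_empty(self, toy_ref):
        _, _, seq = _mature_seq(toy_ref, "mir-a")
        mutated = "CCC" + seq[3:] if all(c != "C" for c in seq[:3]) else "GGG" + seq[3:]
        # ensure 3 mismatches against the source placement and (by Hamming
        # separation of the toy hairpins) more elsewhere
        assert sum(a != b for a, b in zip(mutated, seq)) == 3
        assert align_read(mutated, toy_ref) == []

    def test_two_mismatches_tolerated(self, toy_ref):
        hp, arm, seq = _mature_seq(toy_ref, "mir-b")
        mutated = list(seq)
        for pos in (4, 9):
            mutated[pos] = "A" if seq[pos] != "A" else "C"
        hits = align_read("".join(mutated), toy_ref)
        assert [(h.hairpin_id, h.start, h.mismatches) for h in hits] == [
            (hp.hairpin_id, arm.start, 2)
        ]

    def test_rna_read_matches_dna_reference(self, toy_ref):
        _, arm, seq = _mature_seq(toy_ref, "mir-a")
        assert align_read(seq.replace("T", "U"), toy_ref)[0].start == arm.start

    def test_non_acgt_symbols_count_as_mismatches(self, toy_ref):
        _, arm, seq = _mature_seq(toy_ref, "mir-a")
        assert align_read("NN" + seq[2:], toy_ref)[0].mismatches == 2
        assert align_read("NNN" + seq[3:], toy_ref) == []

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Vectorized scan == exhaustive Hamming oracle, placement for placement."""
        rng = np.random.default_rng(42)
        ref = simulate_reference(SimulationConfig(n_mirnas=20, seed=42))
        mat = [(hp, arm, hp.mature_sequence(arm)) for hp in ref for arm in hp.matures]
        reads = []
        for i in range(500):
            hp, arm, seq = mat[rng.integers(len(mat))]
            s = list(seq)
            for _ in range(rng.integers(0, 4)):  # 0-3 mutations
                p = rng.integers(len(s))
                s[p] = "ACGT"[rng.integers(4)]
            if rng.random() < 0.1:  # some entirely random reads
                s = [rng.choice(list("ACGT")) for _ in range(rng.integers(16, 26))]
            reads.append("".join(s))
        for read in reads:
            got = [
                (a.hairpin_id, a.start, a.mismatches) for a in align_read(read, ref)
            ]
            assert sorted(got) == brute_force_align(read, ref)


class TestAssignToMature:
    def test_exact_start_full_overlap(self, toy_ref):
        hp, arm, seq = _mature_seq(toy_ref, "mir-a")
        aln = Alignment("r", hp.hairpin_id, arm.start, len(seq), 0)
        assert assign_to_mature(aln, toy_ref) == "mir-a"

    def test_loop_read_overlapping_no_arm_unassigned(self, toy_ref):
        hp = toy_ref.entries[0]
        aln = Alignment("r", hp.hairpin_id, 34, 20, 0)  # starts 25 nt past arm 5'
        assert assign_to_mature(aln, toy_ref) is None

    def test_offset_window_boundary(self, toy_ref):
        hp, arm, seq = _mature_seq(toy_ref, "mir-a")
        ok = Alignment("r", hp.hairpin_id, arm.start + 3, len(seq), 0)
        too_far = Alignment("r", hp.hairpin_id, arm.start + 4, len(seq), 0)
        assert assign_to_mature(ok, toy_ref) == "mir-a"
        assert assign_to_mature(too_far, toy_ref) is None

    def test_order_independent_of_reference_entry_order(self, toy_ref):
        flipped = HairpinReference(tuple(reversed(toy_ref.entries)))
        hp, arm, seq = _mature_seq(toy_ref, "mir-b")
        aln = Alignment("r", hp.hairpin_id, arm.start - 1, len(seq), 0)
        assert assign_to_mature(aln, toy_ref) == assign_to_mature(aln, flipped) == "mir-b"

    def test_simulated_isomir_offsets_all_assigned_to_source(self, sim_config, sim_ref):
        cfg = replace(sim_config, reads_per_library=2000, error_rate=0.0, seed=9)
        readsets, _, truth = simulate_libraries(cfg, sim_ref)
        counts, _ = count_libraries([_trimmed(readsets, "cell_nt")], sim_ref)
        expected = (
            truth.read_records["cell_nt"].groupby("mature_id").size().astype(float)
        )
        got = counts.counts["cell_nt"]
        assert (got.loc[expected.index] == expected).all()
        assert got.drop(expected.index).sum() == 0


class TestCountLibraries:
    def test_identical_canonical_reads(self, toy_ref):
        _, _, seq = _mature_seq(toy_ref, "mir-a")
        rs = ReadSet(tuple(Read(f"r{i}", seq) for i in range(10)), "cell")
        counts, isomirs = count_libraries([rs], toy_ref)
        assert counts.counts.loc["mir-a", "cell"] == 10
        assert counts.total_mapped["cell"] == 10
        assert isomirs["cell"].dominant_fraction("mir-a") == 1.0
        assert isomirs["cell"].dominant_class("mir-a") == (0, 0, 0)

    def test_multimapper_split_equally(self):
        mat = "TGAGGTAGTAGGTTGTATAGTT"
        ref = HairpinReference(
            (
                Hairpin("hp1", "GCGTACGT" + mat + "ACCTGGACCTAG", (MatureArm("m1", 9, 30),)),
                Hairpin("hp2", "TTACCGGA" + mat + "CATGGATCCATG", (MatureArm("m2", 9, 30),)),
            )
        )
        rs = ReadSet((Read("r0", mat),), "cell")
        counts, _ = count_libraries([rs], ref)
        assert counts.counts.loc["m1", "cell"] == pytest.approx(0.5)
        assert counts.counts.loc["m2", "cell"] == pytest.approx(0.5)
        discard, _ = count_libraries([rs], ref, multimap="discard")
        assert discard.total_mapped["cell"] == 0
        first, _ = count_libraries([rs], ref, multimap="first-by-id")
        assert first.counts.loc["m1", "cell"] == 1.0

    def test_weight_conservation(self, sim_config, sim_ref):
        cfg = replace(sim_config, reads_per_library=3000, seed=21)
        readsets, _, _ = simulate_libraries(cfg, sim_ref)
        rs = _trimmed(readsets, "EV_nt")
        counts, _ = count_libraries([rs], sim_ref)
        # every assigned read contributes exactly weight 1
        assigned = counts.total_mapped["EV_nt"]
        assert assigned <= len(rs)
        assert counts.counts["EV_nt"].sum() == pytest.approx(assigned)
        # with a 0.1% error rate nearly everything is assignable
        assert assigned > 0.99 * len(rs)

    def test_empty_readset_gives_zero_column(self, toy_ref):
        rs = ReadSet((), "cell")
        counts, _ = count_libraries([rs], toy_ref)
        assert counts.counts["cell"].sum() == 0

    def test_all_matures_self_align_uniquely(self, sim_ref):
        """Every simulated mature maps back to its own arm with 0 mismatches."""
        for hp in sim_ref:
            for arm in hp.matures:
                hits = align_read(hp.mature_sequence(arm), sim_ref)
                assert len(hits) == 1
                assert hits[0].hairpin_id == hp.hairpin_id
                assert hits[0].start == arm.start
                assert hits[0].mismatches == 0
                assert assign_to_mature(hits[0], sim_ref) == arm.mature_id

    def test_dominant_fraction_tracks_canonical_mass(self, sim_ref):
        """With canonical isomiR mass 0.5, the dominant class holds ~half the reads."""
        cfg = SimulationConfig(
            n_mirnas=40, reads_per_library=2000, error_rate=0.0, spike=None, seed=17
        )
        readsets, _, _ = simulate_libraries(cfg, sim_ref)
        counts, isomirs = count_libraries([_trimmed(readsets, "cell_nt")], sim_ref)
        col = counts.counts["cell_nt"]
        big = col[col >= 300].index  # only well-sampled miRNAs
        assert len(big) >= 2
        for mid in big:
            assert isomirs["cell_nt"].dominant_fraction(mid) == pytest.approx(0.5, abs=0.05)
            assert isomirs["cell_nt"].dominant_class(mid) == (0, 0, 0)

    def test_isomir_fractions_sum_to_one_per_mature(self, sim_ref):
        cfg = SimulationConfig(
            n_mirnas=40, reads_per_library=2000, spike=None, seed=19
        )
        readsets, _, _ = simulate_libraries(cfg, sim_ref)
        _, isomirs = count_libraries([_trimmed(readsets, "EV_nt")], sim_ref)
        table = isomirs["EV_nt"].table
        sums = table.groupby("mature_id")["fraction"].sum()
        assert np.allclose(sums.values, 1.0)
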