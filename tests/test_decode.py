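"""Read decoding, bead calling, selectivity filtering, and hit clustering."""

import pytest

from delfold import (
    AcylPosition,
    BeadRead,
    Channel,
    DELMember,
    DecodeFailure,
    FailureReason,
    Fingerprint,
    HubStereo,
    cluster_hits,
    decode_beads,
    encode_member,
    hit_rate,
    match_pattern,
    selectivity_filter,
)
from delfold.decode import HitEntry, HitTable, read_bead_reads
from delfold.simulate import BeadReadSpec, simulate_bead_reads, write_fastq


def member(r1=0, acid=0, pos=AcylPosition.R2):
    return DELMember(r1, acid, pos, HubStereo.S)


class TestMatchPattern:
    def test_round_trip(self, small_scheme):
        m = member(1, 2, AcylPosition.R3)
        triple = match_pattern(encode_member(m, small_scheme), small_scheme)
        assert (triple.r1_index, triple.acid_index, triple.acyl_position) == (
            1, 2, AcylPosition.R3,
        )

    def test_single_substitution_corrected(self, small_scheme):
        # one error inside a codon stays uniquely decodable below half the
        # design distance (min_hamming = 3)
        m = member(0, 1)
        tag = encode_member(m, small_scheme)
        pos = small_scheme.field_slices()[1].start  # first base of acid codon
        corrupted = tag[:pos] + ("A" if tag[pos] != "A" else "C") + tag[pos + 1 :]
        triple = match_pattern(corrupted, small_scheme)
        assert not isinstance(triple, DecodeFailure)
        assert triple.acid_index == 1

    def test_beyond_tolerance_rejected(self, small_scheme):
        # a codon field at Hamming distance >= 2 from every table codon
        # cannot be resolved at max_mismatch 1
        import itertools

        from delfold.encoding import hamming

        m = member(0, 1)
        tag = encode_member(m, small_scheme)
        s = small_scheme.field_slices()[1]
        bad = next(
            "".join(cand)
            for cand in itertools.product("ACGT", repeat=small_scheme.codon_length)
            if min(hamming("".join(cand), c) for c in small_scheme.acid_codons) >= 2
        )
        corrupted = tag[: s.start] + bad + tag[s.stop :]
        result = match_pattern(corrupted, small_scheme)
        assert isinstance(result, DecodeFailure)
        assert result.reason in (
            FailureReason.CODON_UNRESOLVED, FailureReason.CODON_AMBIGUOUS,
        )

    def test_truncated_primer_no_anchor(self, small_scheme):
        tag = encode_member(member(), small_scheme)
        result = match_pattern(tag[3:], small_scheme)
        assert isinstance(result, DecodeFailure)
        assert result.reason is FailureReason.NO_ANCHOR

    def test_truncated_read_fails(self, small_scheme):
        tag = encode_member(member(), small_scheme)
        result = match_pattern(tag[:-4], small_scheme)
        assert isinstance(result, DecodeFailure)


class TestDecodeBeads:
    def test_replicate_classes(self, small_scheme):
        a, b = member(0, 0), member(1, 1)
        reads = []
        for i in range(3):
            reads.append(BeadRead(f"bead{i}", Channel.TARGET,
                                  encode_member(a, small_scheme)))
        reads.append(BeadRead("bead3", Channel.TARGET, encode_member(b, small_scheme)))
        tables, stats = decode_beads(reads, small_scheme)
        target = tables[Channel.TARGET]
        assert target[a.tag_key].k == 3
        assert target[b.tag_key].k == 1
        assert stats.beads_called == 4

    def test_majority_vote(self, small_scheme):
        a, b = member(0, 0), member(1, 1)
        reads = [BeadRead("bead0", Channel.TARGET, encode_member(a, small_scheme))
                 for _ in range(5)]
        reads.append(BeadRead("bead0", Channel.TARGET, encode_member(b, small_scheme)))
        tables, _ = decode_beads(reads, small_scheme)
        assert a.tag_key in tables[Channel.TARGET]
        assert b.tag_key not in tables[Channel.TARGET]

    def test_tie_drops_bead(self, small_scheme):
        a, b = member(0, 0), member(1, 1)
        reads = [
            BeadRead("bead0", Channel.TARGET, encode_member(a, small_scheme)),
            BeadRead("bead0", Channel.TARGET, encode_member(b, small_scheme)),
        ]
        tables, stats = decode_beads(reads, small_scheme)
        assert len(tables[Channel.TARGET]) == 0
        assert stats.beads_dropped_tie == 1
        assert "bead0" in stats.dropped_beads

    def test_total_k_never_exceeds_beads(self, small_scheme):
        spec = BeadReadSpec(
            planted_hits={Channel.TARGET: {member(0, 0): 4, member(1, 2): 2}},
            noise_rate=0.05,
            seed=3,
        )
        reads, truth = simulate_bead_reads(spec, small_scheme)
        tables, _ = decode_beads(reads, small_scheme)
        assert tables[Channel.TARGET].total_k <= len(truth)

    def test_noisy_monte_carlo_accuracy(self, scheme):
        # 100 beads at 1% per-base substitution: the binomial error model
        # (primers exact, codons 1-mismatch-tolerant, 5 reads/bead) puts the
        # per-bead failure probability well below 1%.
        plants = {
            DELMember(i, 2 * i, AcylPosition.R2, HubStereo.S): 10 for i in range(10)
        }
        spec = BeadReadSpec(
            planted_hits={Channel.TARGET: plants}, noise_rate=0.01, seed=7
        )
        reads, truth = simulate_bead_reads(spec, scheme)
        tables, _ = decode_beads(reads, scheme)
        target = tables[Channel.TARGET]
        correct = sum(
            1
            for row in truth.itertuples(index=False)
            if row.compound_key in target
            and row.bead_id in target[row.compound_key].bead_ids
        )
        assert correct >= 95


class TestSelectivityFilter:
    def _table(self, channel, keys):
        entries = {
            k: HitEntry(k, 0, 0, AcylPosition.R2, channel, (f"b{k}",)) for k in keys
        }
        return HitTable(channel=channel, entries=entries)

    def test_removes_shared_compounds(self):
        target = self._table(Channel.TARGET, ["A", "B"])
        counter = self._table(Channel.COUNTER, ["B"])
        kept = selectivity_filter(target, counter)
        assert set(kept.keys()) == {"A"}

    def test_empty_counter_is_identity(self):
        target = self._table(Channel.TARGET, ["A", "B"])
        counter = self._table(Channel.COUNTER, [])
        assert set(selectivity_filter(target, counter).keys()) == {"A", "B"}

    def test_output_subset_and_disjoint(self):
        target = self._table(Channel.TARGET, list("ABCDE"))
        counter = self._table(Channel.COUNTER, list("CDEFG"))
        kept = selectivity_filter(target, counter)
        assert set(kept.keys()) <= set(target.keys())
        assert set(kept.keys()).isdisjoint(counter.keys())


class TestClusterHits:
    def _hits(self, ks):
        entries = {
            key: HitEntry(key, 0, 0, AcylPosition.R2, Channel.TARGET,
                          tuple(f"b{key}{i}" for i in range(k)))
            for key, k in ks.items()
        }
        return HitTable(channel=Channel.TARGET, entries=entries)

    def test_identical_fingerprints_one_cluster(self):
        hits = self._hits({"A": 2, "B": 1, "C": 1})
        fp = lambda key: Fingerprint(frozenset({0, 1}), 4)
        clusters = cluster_hits(hits, fingerprint_fn=fp)
        assert len(clusters) == 1
        assert clusters[0].size == 3
        assert clusters[0].representative == "A"  # max k

    def test_disjoint_fingerprints_singletons(self):
        hits = self._hits({"A": 1, "B": 1, "C": 1})
        fps = {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({2})}
        clusters = cluster_hits(hits, fingerprint_fn=lambda k: Fingerprint(fps[k], 4))
        assert len(clusters) == 3
        assert all(c.size == 1 for c in clusters)

    def test_leader_algorithm_trace(self):
        # pairwise similarities AB=0.9 (not exact but >= 0.8), AC>=0.8, BC=0.5:
        # A (max k) seeds, B and C both join A -> one cluster despite BC < 0.8
        hits = self._hits({"A": 3, "B": 1, "C": 1})
        fps = {
            "A": frozenset({0, 1, 2, 3, 4}),
            "B": frozenset({0, 1, 2, 3, 5}),   # |AB inter|=4, union 6 -> 0.67? no
            "C": frozenset({0, 1, 2, 3, 6}),
        }
        # use 9/10 overlap to get similarity >= 0.8 between A and each of B, C
        fps = {
            "A": frozenset(range(9)),
            "B": frozenset(range(1, 10)),           # |int|=8, |union|=10 -> 0.8
            "C": frozenset({0, 1, 2, 3, 4, 5, 6, 7, 10}),  # vs A: 8/10 = 0.8
        }
        clusters = cluster_hits(
            hits, threshold=0.8, fingerprint_fn=lambda k: Fingerprint(fps[k], 12)
        )
        assert len(clusters) == 1
        assert clusters[0].representative == "A"
        assert set(clusters[0].members) == {"A", "B", "C"}

    def test_partition_and_order_invariance(self, small_scheme):
        from delfold import enumerate_del

        members = list(enumerate_del(small_scheme))[:8]
        entries = {
            m.tag_key: HitEntry(m.tag_key, m.r1_index, m.acid_index,
                                m.acyl_position, Channel.TARGET, ("b",))
            for m in members
        }
        hits1 = HitTable(Channel.TARGET, dict(entries))
        hits2 = HitTable(Channel.TARGET, dict(reversed(list(entries.items()))))
        c1 = cluster_hits(hits1, threshold=0.5)
        c2 = cluster_hits(hits2, threshold=0.5)
        assert c1 == c2
        all_members = [m for c in c1 for m in c.members]
        assert sorted(all_members) == sorted(entries)  # partition


class TestHitRate:
    def test_values(self):
        assert hit_rate(60, 750_000) == pytest.approx(0.008)
        assert hit_rate(0, 1000) == 0.0
        assert hit_rate(750_000, 750_000) == 100.0

    def test_zero_beads_guarded(self):
        with pytest.raises(ValueError):
            hit_rate(1, 0)


def test_fastq_round_trip(tmp_path, small_scheme):
    spec = BeadReadSpec(
        planted_hits={
            Channel.TARGET: {member(0, 0): 2},
            Channel.COUNTER: {member(1, 1): 1},
        },
        seed=5,
    )
    reads, _ = simulate_bead_reads(spec, small_scheme)
    path = tmp_path / "reads.fastq"
    write_fastq(reads, path)
    loaded = read_bead_reads(path)
    assert len(loaded) == len(reads)
    assert {(r.bead_id, r.channel, r.sequence) for r in loaded} == {
        (r.bead_id, r.channel, r.sequence) for r in reads
    }
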