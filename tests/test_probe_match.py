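import numpy as np
import pytest

from xsmm.array_io import ProbeRecord, ValidationError
from xsmm.probe_match import (
    AlignmentParams,
    AlignmentResult,
    AmbiguityError,
    MismatchProbePair,
    align_design,
    align_probe,
    call_mismatch_pairs,
    filter_probesets,
    find_identical_probes,
)


def hamming_oracle(probe: str, consensus: str):
    """Independent brute force: leftmost window minimizing Hamming distance."""
    best = None
    for start in range(len(consensus) - len(probe) + 1):
        window = consensus[start : start + len(probe)]
        mismatches = [i + 1 for i, (a, b) in enumerate(zip(window, probe)) if a != b]
        if best is None or len(mismatches) < len(best[1]):
            best = (start + 1, mismatches)
    return best


def probe(seq, probe_id="p1", probeset_id="ps1", order=1, design="designB"):
    return ProbeRecord(probeset_id, probe_id, order, seq, design)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignProbe:
    def test_exact_substring_coordinates(self, rng):
        consensus = random_seq(rng, 60)
        r = align_probe(probe(consensus[10:35]), consensus, consensus_id="c")
        assert (r.start, r.end, r.gap_count) == (11, 35, 0)
        assert r.probe_fully_aligned and r.mismatch_positions == ()

    def test_single_substitution_reported_with_bases(self, rng):
        consensus = random_seq(rng, 80)
        window = list(consensus[20:45])
        old = window[12]
        window[12] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
        r = align_probe(probe("".join(window)), consensus, consensus_id="c")
        assert r.mismatch_positions == (13,)
        assert r.mismatch_pairs == ((old, window[12]),)

    def test_consensus_too_short(self):
        with pytest.raises(ValidationError, match="shorter"):
            align_probe(probe("A" * 25), "ACGT" * 6, consensus_id="c")

    def test_matches_hamming_oracle_on_planted_instances(self, rng):
        """Planted probes with 0-2 substitutions, no indels: the aligner must
        equal the sliding-window minimum-Hamming oracle exactly."""
        for _ in range(300):
            consensus = random_seq(rng, int(rng.integers(40, 120)))
            start0 = int(rng.integers(0, len(consensus) - 25 + 1))
            window = list(consensus[start0 : start0 + 25])
            for pos in rng.choice(25, size=int(rng.integers(0, 3)), replace=False):
                window[pos] = str(rng.choice([b for b in "ACGT" if b != window[pos]]))
            r = align_probe(probe("".join(window)), consensus, consensus_id="c")
            start, mismatches = hamming_oracle("".join(window), consensus)
            assert r.start == start
            assert list(r.mismatch_positions) == mismatches
            assert r.gap_count == 0 and r.probe_fully_aligned

    def test_gapped_alignment_reports_gaps(self):
        consensus = "TTTTTACGGCAGTACGGTTCCAGTCAGGCATTGCATTTT"
        window = consensus[5:31]  # 26 consensus bases
        deleted = window[:12] + window[13:]  # probe missing one base
        r = align_probe(probe(deleted), consensus, consensus_id="c")
        assert r.gap_count > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            AlignmentParams(gap_open_penalty=-1)
        with pytest.raises(ValidationError):
            AlignmentParams(match_score=-1, mismatch_score=1)


def aln(probe_id, start, fully=True, gaps=0):
    return AlignmentResult(
        probe_id=probe_id,
        consensus_id="c",
        start=start,
        end=start + 24,
        gap_count=gaps,
        probe_fully_aligned=fully,
        mismatch_positions=(),
        mismatch_pairs=(),
    )


class TestFilterProbesets:
    def probes(self, starts, probeset="ps1"):
        return [
            probe("A" * 25, probe_id=f"{probeset}_p{i}", probeset_id=probeset, order=i + 1)
            for i in range(len(starts))
        ]

    def test_sequential_complete_kept(self):
        probes = self.probes([5, 40, 90])
        alignments = {p.probe_id: aln(p.probe_id, s) for p, s in zip(probes, [5, 40, 90])}
        kept, log = filter_probesets(alignments, probes)
        assert kept == {"ps1"} and log.empty

    def test_non_sequential_discarded(self):
        probes = self.probes([40, 5, 90])
        alignments = {p.probe_id: aln(p.probe_id, s) for p, s in zip(probes, [40, 5, 90])}
        kept, log = filter_probesets(alignments, probes)
        assert kept == set()
        assert log.iloc[0].tolist() == ["ps1", "non-sequential"]

    def test_gapped_probe_discards_as_incomplete(self):
        probes = self.probes([5, 40, 90])
        alignments = {p.probe_id: aln(p.probe_id, s) for p, s in zip(probes, [5, 40, 90])}
        alignments["ps1_p1"] = aln("ps1_p1", 40, gaps=1)
        kept, log = filter_probesets(alignments, probes)
        assert kept == set()
        assert log.iloc[0].tolist() == ["ps1", "incomplete"]


class TestCallPairs:
    def setup_instance(self, rng, mutate_at=None, n_mutations=1):
        consensus = {"ps1": random_seq(rng, 60)}
        window = consensus["ps1"][10:35]
        pm = probe(window, probe_id="a1", design="designA")
        mutated = list(window)
        positions = [mutate_at] if mutate_at else []
        if not positions:
            positions = list(rng.choice(25, size=n_mutations, replace=False))
        for pos in positions[:n_mutations]:
            mutated[pos - 1 if mutate_at else pos] = str(
                rng.choice([b for b in "ACGT" if b != mutated[pos - 1 if mutate_at else pos]])
            )
        query = probe("".join(mutated), probe_id="b1")
        alignments = {"b1": align_probe(query, consensus["ps1"], consensus_id="ps1")}
        return consensus, pm, query, alignments

    def test_planted_substitution_recovered(self, rng):
        consensus = {"ps1": "T" * 16 + "C" + "T" * 43}  # consensus base C at probe pos 7
        window = consensus["ps1"][10:35]
        pm = probe(window, probe_id="a1", design="designA")
        mutated = window[:6] + "A" + window[7:]
        query = probe(mutated, probe_id="b1")
        alignments = {"b1": align_probe(query, consensus["ps1"], consensus_id="ps1")}
        result = call_mismatch_pairs(alignments, [query], [pm], consensus)
        (pair,) = result.pairs
        assert (pair.position, pair.mismatch_type) == (7, "C-A")

    def test_two_substitutions_dropped(self, rng):
        consensus, pm, query, alignments = self.setup_instance(rng, n_mutations=2)
        result = call_mismatch_pairs(alignments, [query], [pm], consensus)
        assert result.pairs == [] and result.multi_mismatch_ids == ["b1"]

    def test_zero_mismatch_routed_to_controls(self, rng):
        consensus, pm, _, _ = self.setup_instance(rng)
        query = probe(pm.sequence, probe_id="b1")
        alignments = {"b1": align_probe(query, consensus["ps1"], consensus_id="ps1")}
        result = call_mismatch_pairs(alignments, [query], [pm], consensus)
        assert result.pairs == [] and result.controls == [(pm, query)]

    def test_ambiguous_pm_window_raises(self, rng):
        consensus = {"ps3": random_seq(rng, 60)}
        window = consensus["ps3"][0:25]
        pm1 = probe(window, probe_id="a1", probeset_id="ps1", design="designA")
        pm2 = probe(window, probe_id="a2", probeset_id="ps2", design="designA")
        mutated = ("A" if window[4] != "A" else "C") + window[1:]
        query = probe(mutated[:25], probe_id="b1", probeset_id="ps3")
        alignments = {"b1": align_probe(query, consensus["ps3"], consensus_id="ps3")}
        with pytest.raises(AmbiguityError, match="a1.*a2"):
            call_mismatch_pairs(alignments, [query], [pm1, pm2], consensus)

    def test_output_invariant_to_input_order(self, noiseless_experiment):
        exp = noiseless_experiment
        alignments = align_design(exp["design_b"], exp["consensus"])
        kept, _ = filter_probesets(alignments, exp["design_b"])
        forward = call_mismatch_pairs(
            alignments, exp["design_b"], exp["design_a"], exp["consensus"], kept
        )
        backward = call_mismatch_pairs(
            alignments, exp["design_b"][::-1], exp["design_a"][::-1], exp["consensus"], kept
        )
        assert forward.pairs == backward.pairs

    def test_no_probe_in_both_pairs_and_controls(self, noiseless_experiment):
        exp = noiseless_experiment
        alignments = align_design(exp["design_b"], exp["consensus"])
        kept, _ = filter_probesets(alignments, exp["design_b"])
        result = call_mismatch_pairs(
            alignments, exp["design_b"], exp["design_a"], exp["consensus"], kept
        )
        in_pairs = {p.mm_probe.probe_id for p in result.pairs}
        in_controls = {b.probe_id for _, b in result.controls}
        assert not (in_pairs & in_controls)


class TestIdenticalProbes:
    def test_all_paired_when_designs_identical(self, rng):
        a = [probe(random_seq(rng, 25), probe_id=f"a{i}", design="designA") for i in range(20)]
        b = [
            ProbeRecord(p.probeset_id, f"b{i}", p.order_index, p.sequence, "designB")
            for i, p in enumerate(a)
        ]
        pairs = find_identical_probes(a, b)
        assert len(pairs) == 20

    def test_disjoint_sets_empty(self):
        a = [probe("A" * 25, probe_id="a1", design="designA")]
        b = [probe("C" * 25, probe_id="b1")]
        assert find_identical_probes(a, b) == []

    def test_shared_probeset_preferred(self):
        seq = "ACGT" * 6 + "A"
        a1 = probe(seq, probe_id="a1", probeset_id="psX", design="designA")
        a2 = probe(seq, probe_id="a0", probeset_id="psY", design="designA")
        b = probe(seq, probe_id="b1", probeset_id="psX")
        assert find_identical_probes([a1, a2], [b]) == [(a1, b)]


class TestMismatchProbePairValidation:
    def test_position_and_type_must_match_sequences(self):
        pm = probe("A" * 25, probe_id="a1", design="designA")
        mm = probe("A" * 12 + "G" + "A" * 12, probe_id="b1")
        pair = MismatchProbePair("ps1", pm, mm, 13, "A-G")
        assert pair.pair_id == "a1|b1"
        with pytest.raises(ValidationError, match="differ at offsets"):
            MismatchProbePair("ps1", pm, mm, 12, "A-G")
        with pytest.raises(ValidationError, match="spell"):
            MismatchProbePair("ps1", pm, mm, 13, "A-C")
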