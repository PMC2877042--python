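"""Discovery of single-base mismatch probe pairs between two array designs.

The procedure mirrors the five steps used to mine cross-design pairs from a
cross-species hybridization: (1) obtain the consensus transcript sequences,
(2) align every probe of the query design to its probeset's consensus with a
semi-global aligner, (3) discard probesets whose probes do not align
sequentially or completely, (4) keep probes with exactly one mismatch to the
consensus (these act as MM probes), and (5) look up, in the other design, the
probe whose sequence equals the aligned consensus window (the PM probe).
Probes identical between the designs serve as controls.

Alignment is semi-global: the probe is aligned end-to-end while end gaps on
the consensus are free.  The score scale (match +1, mismatch -1, gap open 5,
gap extend 0.5) guarantees that for 25-mers a single substitution always
scores better than any gapped alternative, so on indel-free data the aligner
reduces exactly to a minimum-Hamming-distance window scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .array_io import ProbeRecord, ValidationError
from .constants import PROBE_LENGTH


class AmbiguityError(ValueError):
    """A consensus window matches probes on more than one conflicting probeset."""


@dataclass(frozen=True)
class AlignmentParams:
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open_penalty: float = 5.0
    gap_extend_penalty: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open_penalty < 0 or self.gap_extend_penalty < 0:
            raise ValidationError("gap penalties must be >= 0")
        if self.match_score <= self.mismatch_score:
            raise ValidationError("match_score must exceed mismatch_score")


@dataclass(frozen=True)
class AlignmentResult:
    """Placement of one probe on its consensus.

    ``start``/``end`` are 1-based inclusive consensus coordinates of the
    aligned probe span.  ``mismatch_positions`` are probe coordinates
    (1 = 5'-most base of the probe as written, 25 = 3'-most), sorted
    ascending; ``mismatch_pairs`` are the corresponding
    (consensus base, probe base) pairs.
    """

    probe_id: str
    consensus_id: str
    start: int
    end: int
    gap_count: int
    probe_fully_aligned: bool
    mismatch_positions: tuple[int, ...]
    mismatch_pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class MismatchProbePair:
    """A PM/MM probe duo: the atom of the whole analysis.

    ``position`` (1..25) is where the single substitution sits on the probe;
    ``mismatch_type`` is PM base -> MM base (the PM base equals the consensus
    base, since the PM probe matches the consensus window exactly).
    """

    probeset_id: str
    pm_probe: ProbeRecord
    mm_probe: ProbeRecord
    position: int
    mismatch_type: str

    def __post_init__(self) -> None:
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(self.pm_probe.sequence, self.mm_probe.sequence))
            if a != b
        ]
        if diffs != [self.position]:
            raise ValidationError(
                f"pair {self.pm_probe.probe_id}/{self.mm_probe.probe_id}: sequences "
                f"differ at offsets {diffs}, not solely at position {self.position}"
            )
        expected = (
            f"{self.pm_probe.sequence[self.position - 1]}-"
            f"{self.mm_probe.sequence[self.position - 1]}"
        )
        if expected != self.mismatch_type:
            raise ValidationError(
                f"pair {self.pm_probe.probe_id}/{self.mm_probe.probe_id}: bases spell "
                f"{expected}, not {self.mismatch_type}"
            )

    @property
    def pair_id(self) -> str:
        return f"{self.pm_probe.probe_id}|{self.mm_probe.probe_id}"


@dataclass
class MatchResult:
    """Output of pair calling: mismatch pairs, exact-match controls, drops."""

    pairs: list[MismatchProbePair]
    controls: list[tuple[ProbeRecord, ProbeRecord]]  # (pm-design, query-design)
    multi_mismatch_ids: list[str]
    unmatched_window_ids: list[str] = field(default_factory=list)


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = -(params.gap_open_penalty + params.gap_extend_penalty)
    aligner.extend_gap_score = -params.gap_extend_penalty
    # consensus overhangs beyond the probe span are free (semi-global): they
    # appear as end gaps in the probe (query) row when aligning
    # (consensus, probe), i.e. end deletions in Biopython's naming
    if hasattr(aligner, "open_end_deletion_score"):
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # older Bio.Align naming
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_ungapped(probe: str, consensus: str) -> tuple[int, np.ndarray]:
    """Leftmost minimum-Hamming window: (0-based start, boolean mismatch mask)."""
    c = _encode(consensus)
    p = _encode(probe)
    windows = np.lib.stride_tricks.sliding_window_view(c, len(p))
    mism = windows != p
    counts = mism.sum(axis=1)
    start = int(np.argmin(counts))  # argmin returns the leftmost minimum
    return start, mism[start]


def align_probe(
    probe: ProbeRecord, consensus: str, params: AlignmentParams | None = None,
    consensus_id: str = "",
) -> AlignmentResult:
    """Semi-global alignment of a 25-mer probe against a consensus sequence.

    Ties are broken deterministically: leftmost start, then fewest gaps.  An
    ungapped placement is returned whenever it attains the optimal score.
    """
    params = params or AlignmentParams()
    if len(consensus) < PROBE_LENGTH:
        raise ValidationError(
            f"consensus {consensus_id!r} (length {len(consensus)}) shorter than "
            f"probe length {PROBE_LENGTH}"
        )
    seq = probe.sequence
    start0, mask = _best_ungapped(seq, consensus)
    ungapped_score = (
        (PROBE_LENGTH - mask.sum()) * params.match_score + mask.sum() * params.mismatch_score
    )

    aligner = _make_aligner(params)
    optimal = aligner.score(consensus, seq)

    if ungapped_score >= optimal - 1e-9:
        positions = tuple(int(i) + 1 for i in np.flatnonzero(mask))
        pairs = tuple(
            (consensus[start0 + i - 1], seq[i - 1]) for i in positions
        )
        return AlignmentResult(
            probe_id=probe.probe_id,
            consensus_id=consensus_id,
            start=start0 + 1,
            end=start0 + PROBE_LENGTH,
            gap_count=0,
            probe_fully_aligned=True,
            mismatch_positions=positions,
            mismatch_pairs=pairs,
        )
    return _gapped_result(probe, consensus, consensus_id, aligner)


def _gapped_result(
    probe: ProbeRecord, consensus: str, consensus_id: str,
    aligner: Align.PairwiseAligner,
) -> AlignmentResult:
    """Traceback path for the rare case where the optimum requires gaps."""
    candidates = list(itertools.islice(aligner.align(consensus, probe.sequence), 64))

    def describe(aln):
        tgt_blocks, qry_blocks = aln.aligned
        aligned_cols = int(sum(e - s for s, e in qry_blocks))
        t_start, t_end = int(tgt_blocks[0][0]), int(tgt_blocks[-1][1])
        q_start, q_end = int(qry_blocks[0][0]), int(qry_blocks[-1][1])
        internal = (t_end - t_start - aligned_cols) + (q_end - q_start - aligned_cols)
        probe_end_gaps = q_start + (PROBE_LENGTH - q_end)
        return t_start, t_end, internal + probe_end_gaps, aligned_cols

    candidates.sort(key=lambda a: (describe(a)[0], describe(a)[2]))
    best = candidates[0]
    t_start, t_end, gap_count, aligned_cols = describe(best)

    positions: list[int] = []
    pairs: list[tuple[str, str]] = []
    tgt_blocks, qry_blocks = best.aligned
    for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
        for k in range(te - ts):
            cb, pb = consensus[ts + k], probe.sequence[qs + k]
            if cb != pb:
                positions.append(qs + k + 1)
                pairs.append((cb, pb))
    return AlignmentResult(
        probe_id=probe.probe_id,
        consensus_id=consensus_id,
        start=t_start + 1,
        end=t_end,
        gap_count=gap_count,
        probe_fully_aligned=(aligned_cols == PROBE_LENGTH),
        mismatch_positions=tuple(positions),
        mismatch_pairs=tuple(pairs),
    )


def align_design(
    probes: Sequence[ProbeRecord],
    consensus_set: Mapping[str, str],
    probeset_to_consensus: Mapping[str, str] | None = None,
    params: AlignmentParams | None = None,
) -> dict[str, AlignmentResult]:
    """Align every probe to its probeset's consensus.

    By default the consensus id is assumed to equal the probeset id; an
    explicit probeset -> consensus mapping overrides that.
    """
    results: dict[str, AlignmentResult] = {}
    for probe in probes:
        cid = (
            probeset_to_consensus[probe.probeset_id]
            if probeset_to_consensus is not None
            else probe.probeset_id
        )
        if cid not in consensus_set:
            raise ValidationError(
                f"no consensus {cid!r} for probeset {probe.probeset_id!r}"
            )
        results[probe.probe_id] = align_probe(
            probe, consensus_set[cid], params, consensus_id=cid
        )
    return results


def filter_probesets(
    alignments: Mapping[str, AlignmentResult], probes: Sequence[ProbeRecord]
) -> tuple[set[str], pd.DataFrame]:
    """Keep probesets whose probes align sequentially and completely.

    Sequential: alignment start coordinates strictly increase with the
    probe's order_index.  Complete: every probe fully aligned with zero gaps.
    The discard log names the first violated criterion per probeset.
    """
    by_set: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        by_set.setdefault(p.probeset_id, []).append(p)

    kept: set[str] = set()
    discards: list[tuple[str, str]] = []
    for probeset_id, members in sorted(by_set.items()):
        members = sorted(members, key=lambda p: p.order_index)
        if len({p.order_index for p in members}) != len(members):
            raise ValidationError(
                f"probeset {probeset_id!r}: duplicate order_index values"
            )
        alns = [alignments[p.probe_id] for p in members]
        starts = [a.start for a in alns]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            discards.append((probeset_id, "non-sequential"))
            continue
        if any(not a.probe_fully_aligned or a.gap_count > 0 for a in alns):
            discards.append((probeset_id, "incomplete"))
            continue
        kept.add(probeset_id)
    log = pd.DataFrame(discards, columns=["probeset_id", "reason"])
    return kept, log


def call_mismatch_pairs(
    alignments: Mapping[str, AlignmentResult],
    query_probes: Sequence[ProbeRecord],
    pm_probes: Sequence[ProbeRecord],
    consensus_set: Mapping[str, str],
    kept_probesets: set[str] | None = None,
) -> MatchResult:
    """Call single-mismatch PM/MM pairs from filtered alignments.

    A pair is emitted iff the query probe aligns with exactly one mismatch
    (no gaps) and the PM design contains a probe exactly matching the aligned
    consensus window.  Zero-mismatch probes are routed to the control set;
    probes with two or more mismatches are dropped.
    """
    pm_by_seq: dict[str, list[ProbeRecord]] = {}
    for p in pm_probes:
        pm_by_seq.setdefault(p.sequence, []).append(p)

    result = MatchResult(pairs=[], controls=[], multi_mismatch_ids=[])
    for probe in sorted(query_probes, key=lambda p: p.probe_id):
        if kept_probesets is not None and probe.probeset_id not in kept_probesets:
            continue
        aln = alignments[probe.probe_id]
        if not aln.probe_fully_aligned or aln.gap_count > 0:
            continue
        n_mm = len(aln.mismatch_positions)
        if n_mm >= 2:
            result.multi_mismatch_ids.append(probe.probe_id)
            continue
        window = consensus_set[aln.consensus_id][aln.start - 1 : aln.end]
        pm_probe = _resolve_pm_probe(pm_by_seq.get(window, []), probe, window)
        if pm_probe is None:
            result.unmatched_window_ids.append(probe.probe_id)
            continue
        if n_mm == 0:
            result.controls.append((pm_probe, probe))
            continue
        position = aln.mismatch_positions[0]
        consensus_base, probe_base = aln.mismatch_pairs[0]
        result.pairs.append(
            MismatchProbePair(
                probeset_id=probe.probeset_id,
                pm_probe=pm_probe,
                mm_probe=probe,
                position=position,
                mismatch_type=f"{consensus_base}-{probe_base}",
            )
        )
    return result


def _resolve_pm_probe(
    candidates: list[ProbeRecord], query: ProbeRecord, window: str
) -> ProbeRecord | None:
    if not candidates:
        return None
    same_set = sorted(
        (c for c in candidates if c.probeset_id == query.probeset_id),
        key=lambda c: c.probe_id,
    )
    if same_set:
        return same_set[0]
    if len(candidates) == 1:
        return candidates[0]
    raise AmbiguityError(
        f"window {window} for query probe {query.probe_id!r} matches PM probes on "
        f"conflicting probesets: "
        + ", ".join(f"{c.probe_id} ({c.probeset_id})" for c in sorted(candidates, key=lambda c: c.probe_id))
    )


def find_identical_probes(
    design_a: Sequence[ProbeRecord], design_b: Sequence[ProbeRecord]
) -> list[tuple[ProbeRecord, ProbeRecord]]:
    """Control pairs: probes with bitwise-equal 25-mer sequences in both designs.

    Each design-b probe is matched to at most one design-a probe: first by a
    shared probeset_id, otherwise to the lexicographically smallest probe_id.
    """
    a_by_seq: dict[str, list[ProbeRecord]] = {}
    for p in design_a:
        a_by_seq.setdefault(p.sequence, []).append(p)
    pairs: list[tuple[ProbeRecord, ProbeRecord]] = []
    for b in sorted(design_b, key=lambda p: p.probe_id):
        candidates = a_by_seq.get(b.sequence)
        if not candidates:
            continue
        same_set = sorted(
            (c for c in candidates if c.probeset_id == b.probeset_id),
            key=lambda c: c.probe_id,
        )
        chosen = same_set[0] if same_set else min(candidates, key=lambda c: c.probe_id)
        pairs.append((chosen, b))
    return pairs


def pairs_to_frame(pairs: Iterable[MismatchProbePair]) -> pd.DataFrame:
    """Tabular form of a pair list (the `pairs.tsv` artifact)."""
    return pd.DataFrame(
        [
            {
                "probeset_id": p.probeset_id,
                "pm_probe_id": p.pm_probe.probe_id,
                "mm_probe_id": p.mm_probe.probe_id,
                "position": p.position,
                "mismatch_type": p.mismatch_type,
            }
            for p in pairs
        ],
        columns=["probeset_id", "pm_probe_id", "mm_probe_id", "position", "mismatch_type"],
    )
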