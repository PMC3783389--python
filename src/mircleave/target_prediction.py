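"""Plant miRNA target-site search with weighted complementarity scoring.

Plant miRNAs pair near-perfectly, antiparallel, with their target mRNAs, and
Argonaute slices the target between the bases paired to miRNA nucleotides 10
and 11 (counting from the miRNA 5' end).  A candidate site is scored as a sum
of pairing penalties:

* Watson-Crick pair (A:U, G:C) ............ 0
* G:U wobble pair .......................... 0.5
* mismatched pair .......................... 1
* single-nucleotide bulge (either strand) .. 1

Mismatch and G:U penalties are doubled when the miRNA position falls inside
the 5'-proximal *core segment* (positions 2-13 by default), reflecting the
importance of 5' complementarity for slicing.  Sites at or below a penalty
cutoff (default 4) are reported.  By convention the reported cleavage site is
the transcript base paired to miRNA nucleotide 10; for an ungapped site whose
range ends at E (the base paired to the miRNA 5' end) this is E - 9.

The search is a banded fitting alignment: the whole miRNA must be consumed,
the transcript is free at both ends, at most one bulge is allowed (band width
1), and bulges are forbidden opposite miRNA positions 9-12 so the cleavage
position is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import re

from .formats import SequenceRecord, TargetTableRow

_INF = float("inf")

#: miRNA positions opposite which bulges are disallowed (keeps the slicer
#: position, miRNA nt 10, paired).
BULGE_FORBIDDEN_RANGE = (9, 12)


class PairState(str, Enum):
    MATCH = "MATCH"
    GU = "GU"
    MISMATCH = "MISMATCH"
    BULGE_MIRNA = "BULGE_MIRNA"  # miRNA nt unpaired
    BULGE_TARGET = "BULGE_TARGET"  # transcript nt unpaired


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def classify_pair(mirna_nt: str, target_nt: str) -> PairState:
    """Classify one miRNA:target base pair.

    Watson-Crick pairs are MATCH, G:U (either orientation) is GU, everything
    else — including N on the transcript side — is MISMATCH.
    """
    duplex = (mirna_nt, target_nt)
    if duplex in _WC:
        return PairState.MATCH
    if duplex in _WOBBLE:
        return PairState.GU
    return PairState.MISMATCH


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty weights for the weighted-complementarity score."""

    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    bulge_penalty: float = 1.0
    core_range: tuple[int, int] = (2, 13)
    core_multiplier: float = 2.0
    max_bulges: int = 1
    cutoff: float = 4.0
    double_bulges_in_core: bool = False

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gu_penalty, self.bulge_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.core_range[0] < 1 or self.core_range[0] > self.core_range[1]:
            raise ValueError(f"invalid core range {self.core_range}")

    def in_core(self, mirna_pos: int) -> bool:
        lo, hi = self.core_range
        return lo <= mirna_pos <= hi

    def pair_penalty(self, state: PairState, mirna_pos: int) -> float:
        """Penalty contributed by one pairing state at a miRNA position.

        For BULGE_TARGET the bookkeeping position is the next paired miRNA
        nucleotide; core doubling applies to bulges only when
        ``double_bulges_in_core`` is set.
        """
        if state is PairState.MATCH:
            return 0.0
        if state is PairState.GU:
            p = self.gu_penalty
            doubled = self.in_core(mirna_pos)
        elif state is PairState.MISMATCH:
            p = self.mismatch_penalty
            doubled = self.in_core(mirna_pos)
        else:
            p = self.bulge_penalty
            doubled = self.double_bulges_in_core and self.in_core(mirna_pos)
        return p * self.core_multiplier if doubled else p


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class PairingMap:
    """An explicit miRNA:transcript alignment.

    ``steps`` is an ordered tuple of ``(state, mirna_pos, transcript_pos)``
    walking the miRNA 5'->3' (and the transcript 3'->5', since the duplex is
    antiparallel).  ``mirna_pos`` is None for BULGE_TARGET steps and
    ``transcript_pos`` is None for BULGE_MIRNA steps.
    """

    steps: tuple[tuple[PairState, int | None, int | None], ...]

    def __post_init__(self) -> None:
        mirna_positions = [m for _, m, _ in self.steps if m is not None]
        if not mirna_positions:
            raise ValueError("empty pairing")
        expect = list(range(1, max(mirna_positions) + 1))
        if mirna_positions != expect:
            raise ValueError("miRNA positions must be consumed exactly once, in order")
        t_positions = sorted(t for _, _, t in self.steps if t is not None)
        if t_positions != list(range(t_positions[0], t_positions[-1] + 1)):
            raise ValueError("transcript positions must form a contiguous range")

    @property
    def mirna_length(self) -> int:
        return max(m for _, m, _ in self.steps if m is not None)

    @property
    def transcript_range(self) -> tuple[int, int]:
        ts = [t for _, _, t in self.steps if t is not None]
        return (min(ts), max(ts))

    @property
    def n_bulges(self) -> int:
        return sum(1 for s, _, _ in self.steps if s in (PairState.BULGE_MIRNA, PairState.BULGE_TARGET))

    def transcript_position_of(self, mirna_pos: int) -> int | None:
        """Transcript base paired to a given miRNA nucleotide, if any."""
        for state, m, t in self.steps:
            if m == mirna_pos and t is not None:
                return t
        return None


def ungapped_pairing(
    mirna: str, transcript: str, end: int, states: Sequence[PairState] | None = None
) -> PairingMap:
    """Build the ungapped pairing of a miRNA whose 5' end pairs transcript
    position ``end`` (1-based).  If ``states`` is omitted, each pair is
    classified from the sequences."""
    L = len(mirna)
    steps = []
    for i in range(1, L + 1):
        t = end - (i - 1)
        state = states[i - 1] if states is not None else classify_pair(mirna[i - 1], transcript[t - 1])
        steps.append((state, i, t))
    return PairingMap(steps=tuple(steps))


def score_pairing(pairing: PairingMap, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Sum of pairing penalties under a scoring scheme.

    MATCH adds 0; GU adds ``gu_penalty``; MISMATCH adds ``mismatch_penalty``
    (both doubled inside the core); bulges add ``bulge_penalty``.  A
    BULGE_TARGET step takes the miRNA position of the next paired nucleotide
    for core bookkeeping.
    """
    total = 0.0
    steps = pairing.steps
    for idx, (state, m, _t) in enumerate(steps):
        if state is PairState.BULGE_TARGET:
            nxt = next((mm for _, mm, _ in steps[idx + 1 :] if mm is not None), None)
            pos = nxt if nxt is not None else pairing.mirna_length
        else:
            pos = m  # type: ignore[assignment]
        total += scheme.pair_penalty(state, pos)
    return total


@dataclass(frozen=True)
class TargetSite:
    """A scored miRNA target site on one transcript."""

    mirna_id: str
    transcript_id: str
    pairing: PairingMap
    score: float
    start: int
    end: int
    cleavage_position: int

    @property
    def n_bulges(self) -> int:
        return self.pairing.n_bulges


def expected_cleavage_position(pairing: PairingMap) -> int:
    """Transcript base paired to miRNA nucleotide 10 (the slicer position).

    For an ungapped site with range end E this equals E - 9.
    """
    t = pairing.transcript_position_of(10)
    if t is None:
        raise ValueError("miRNA position 10 is unpaired; cleavage position undefined")
    return t


def _bulge_forbidden(mirna_pos: int) -> bool:
    lo, hi = BULGE_FORBIDDEN_RANGE
    return lo <= mirna_pos <= hi


def _enumerate_pairings_at(
    mirna: str, transcript: str, end: int, scheme: ScoringScheme
) -> list[PairingMap]:
    """All legal pairings whose miRNA 5' end pairs transcript position ``end``.

    Legal means: whole miRNA consumed, at most ``scheme.max_bulges`` bulges
    (band width 1), no bulge bookkeeping position in the forbidden 9-12
    window, no terminal transcript bulges, and all transcript positions >= 1.
    """
    L = len(mirna)
    out: list[PairingMap] = []
    if end - L + 1 >= 1:
        out.append(ungapped_pairing(mirna, transcript, end))
    if scheme.max_bulges < 1:
        return out
    # one miRNA bulge at position b: miRNA b unpaired, span L-1
    if end - L + 2 >= 1:
        for b in range(1, L + 1):
            if _bulge_forbidden(b):
                continue
            steps: list[tuple[PairState, int | None, int | None]] = []
            t = end
            for i in range(1, L + 1):
                if i == b:
                    steps.append((PairState.BULGE_MIRNA, i, None))
                else:
                    steps.append((classify_pair(mirna[i - 1], transcript[t - 1]), i, t))
                    t -= 1
            out.append(PairingMap(steps=tuple(steps)))
    # one transcript bulge between miRNA positions k-1 and k (k = 2..L): span L+1
    if end - L >= 1:
        for k in range(2, L + 1):
            if _bulge_forbidden(k):
                continue
            steps = []
            t = end
            for i in range(1, L + 1):
                if i == k:
                    steps.append((PairState.BULGE_TARGET, None, t))
                    t -= 1
                steps.append((classify_pair(mirna[i - 1], transcript[t - 1]), i, t))
                t -= 1
            out.append(PairingMap(steps=tuple(steps)))
    return out


def _min_score_at(mirna: str, transcript: str, end: int, scheme: ScoringScheme) -> float:
    """Banded DP: minimal penalty of any legal pairing anchored at ``end``.

    States are (miRNA positions consumed, bulge status) with bulge status in
    {none, miRNA-bulge used, transcript-bulge used}; band width 1.
    """
    L = len(mirna)
    # cost[b] after consuming i miRNA nts; transcript consumed = i - (b==1) + (b==2)
    cost = [0.0, _INF, _INF]
    allow_bulges = scheme.max_bulges >= 1
    for i in range(0, L):
        nxt = [_INF, _INF, _INF]
        mpos = i + 1
        for b in range(3):
            c = cost[b]
            if c == _INF:
                continue
            consumed = i - (1 if b == 1 else 0) + (1 if b == 2 else 0)
            p = end - consumed
            # transcript bulge before pairing mpos (internal only, once)
            if (
                allow_bulges
                and b == 0
                and 1 <= i <= L - 1
                and not _bulge_forbidden(mpos)
                and p >= 1
                and p - 1 >= 1
            ):
                cb = c + scheme.pair_penalty(PairState.BULGE_TARGET, mpos)
                pen = scheme.pair_penalty(classify_pair(mirna[mpos - 1], transcript[p - 2]), mpos)
                if cb + pen < nxt[2]:
                    nxt[2] = cb + pen
            # pair mpos
            if p >= 1:
                pen = scheme.pair_penalty(classify_pair(mirna[mpos - 1], transcript[p - 1]), mpos)
                if c + pen < nxt[b]:
                    nxt[b] = c + pen
            # miRNA bulge at mpos
            if allow_bulges and b == 0 and not _bulge_forbidden(mpos):
                pen = scheme.pair_penalty(PairState.BULGE_MIRNA, mpos)
                if c + pen < nxt[1]:
                    nxt[1] = c + pen
        cost = nxt
    return min(cost)


def _candidate_order_key(pairing: PairingMap, score: float) -> tuple:
    """Total order used to pick among tied candidates: lower score, fewer
    bulges, leftmost start, then a deterministic structural key."""
    start, end = pairing.transcript_range
    has_target_bulge = any(s is PairState.BULGE_TARGET for s, _, _ in pairing.steps)
    bulge_pos = next(
        (i for i, (s, _, _) in enumerate(pairing.steps) if s in (PairState.BULGE_MIRNA, PairState.BULGE_TARGET)),
        -1,
    )
    return (score, pairing.n_bulges, start, end, int(has_target_bulge), bulge_pos)


def find_sites(
    mirna: SequenceRecord,
    transcript: SequenceRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[TargetSite]:
    """Find every target site of ``mirna`` on ``transcript`` scoring <= cutoff.

    A banded dynamic program scans each anchor position (the transcript base
    paired to the miRNA 5' end); anchors whose minimal fitting-alignment
    penalty is within the cutoff are reconstructed explicitly.  Overlapping
    placements are collapsed to the best-scoring one (ties: fewest bulges,
    then leftmost).  Sites are returned sorted by transcript start.
    """
    m = mirna.residues
    t = transcript.residues
    L = len(m)
    if not (19 <= L <= 24):
        raise ValueError(f"miRNA length {L} outside the expected 19-24 nt range")
    if "N" in m:
        raise ValueError(f"miRNA {mirna.id!r} contains N")
    if len(t) < L:
        return []
    candidates: list[tuple[tuple, PairingMap, float]] = []
    for end in range(L - 1, len(t) + 1):  # allow one-shorter span (miRNA bulge)
        best = _min_score_at(m, t, end, scheme)
        if best > scheme.cutoff:
            continue
        for pairing in _enumerate_pairings_at(m, t, end, scheme):
            score = score_pairing(pairing, scheme)
            if score <= scheme.cutoff:
                candidates.append((_candidate_order_key(pairing, score), pairing, score))
    candidates.sort(key=lambda c: c[0])
    kept: list[tuple[PairingMap, float]] = []
    occupied: list[tuple[int, int]] = []
    for _key, pairing, score in candidates:
        start, end = pairing.transcript_range
        if any(start <= e and s <= end for s, e in occupied):
            continue
        kept.append((pairing, score))
        occupied.append((start, end))
    sites = [
        TargetSite(
            mirna_id=mirna.id,
            transcript_id=transcript.id,
            pairing=pairing,
            score=score,
            start=pairing.transcript_range[0],
            end=pairing.transcript_range[1],
            cleavage_position=expected_cleavage_position(pairing),
        )
        for pairing, score in kept
    ]
    sites.sort(key=lambda s: s.start)
    return sites


_FAMILY_RE = re.compile(r"(miR\d+|MIR\d+)", re.IGNORECASE)


def mirna_family(name: str) -> str:
    """Extract the miRNA family (e.g. 'miR156') from a miRNA name."""
    m = _FAMILY_RE.search(name)
    return "miR" + re.sub(r"\D", "", m.group(0)) if m else name


def predict_targets(
    mirnas: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    annotations: dict[str, str] | None = None,
) -> list[TargetTableRow]:
    """Score every miRNA against every transcript and tabulate the hits.

    Rows follow miRNA input order, then transcript input order, then site
    start.  Duplicate sequence ids are rejected.
    """
    for records, what in ((mirnas, "miRNA"), (transcripts, "transcript")):
        ids = [r.id for r in records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate {what} id {dup!r}")
    annotations = annotations or {}
    rows = []
    for mi in mirnas:
        for tr in transcripts:
            for site in find_sites(mi, tr, scheme):
                rows.append(
                    TargetTableRow(
                        family=mirna_family(mi.id),
                        mirna=mi.id,
                        transcript=tr.id,
                        annotation=annotations.get(tr.id, ""),
                        score=site.score,
                        start=site.start,
                        end=site.end,
                        cleavage_site=site.cleavage_position,
                        category="",
                    )
                )
    return rows
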