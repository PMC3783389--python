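"""Weighted-complementarity scoring and target-site search.

The search is checked against an exhaustive oracle that enumerates every
anchor and every legal <=1-bulge placement independently of the banded scan.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mircleave.formats import SequenceRecord, reverse_complement
from mircleave.target_prediction import (
    DEFAULT_SCHEME,
    PairState,
    PairingMap,
    ScoringScheme,
    classify_pair,
    expected_cleavage_position,
    find_sites,
    mirna_family,
    predict_targets,
    score_pairing,
    ungapped_pairing,
)
from mircleave import synthetic as syn


# ---------------------------------------------------------------------------
# Independent oracles


def oracle_score(pairing: PairingMap, scheme: ScoringScheme) -> float:
    """Per-position summation from the rule table, written independently."""
    rules = {
        PairState.MATCH: 0.0,
        PairState.GU: scheme.gu_penalty,
        PairState.MISMATCH: scheme.mismatch_penalty,
        PairState.BULGE_MIRNA: scheme.bulge_penalty,
        PairState.BULGE_TARGET: scheme.bulge_penalty,
    }
    total = 0.0
    steps = list(pairing.steps)
    for idx, (state, mpos, _tpos) in enumerate(steps):
        penalty = rules[state]
        if state is PairState.BULGE_TARGET:
            following = [m for _, m, _ in steps[idx:] if m is not None]
            book = following[0] if following else max(m for _, m, _ in steps if m is not None)
        else:
            book = mpos
        core = scheme.core_range[0] <= book <= scheme.core_range[1]
        if core and state in (PairState.GU, PairState.MISMATCH):
            penalty *= scheme.core_multiplier
        if core and state in (PairState.BULGE_MIRNA, PairState.BULGE_TARGET):
            if scheme.double_bulges_in_core:
                penalty *= scheme.core_multiplier
        total += penalty
    return total


def oracle_enumerate_sites(mirna, transcript, scheme):
    """Brute-force enumeration over all anchors and <=1-bulge placements.

    Builds every legal pairing explicitly, scores with score_pairing, keeps
    placements within the cutoff, and collapses overlaps with the documented
    tie-break (score, bulges, start, then structural key).
    """
    m, t = mirna.residues, transcript.residues
    L, N = len(m), len(t)
    candidates = []
    for end in range(1, N + 1):
        pairings = []
        if end - L + 1 >= 1:
            pairings.append(ungapped_pairing(m, t, end))
        if scheme.max_bulges >= 1:
            if end - L + 2 >= 1:
                for b in range(1, L + 1):
                    if 9 <= b <= 12:
                        continue
                    steps, tpos = [], end
                    for i in range(1, L + 1):
                        if i == b:
                            steps.append((PairState.BULGE_MIRNA, i, None))
                        else:
                            steps.append((classify_pair(m[i - 1], t[tpos - 1]), i, tpos))
                            tpos -= 1
                    pairings.append(PairingMap(steps=tuple(steps)))
            if end - L >= 1:
                for k in range(2, L + 1):
                    if 9 <= k <= 12:
                        continue
                    steps, tpos = [], end
                    for i in range(1, L + 1):
                        if i == k:
                            steps.append((PairState.BULGE_TARGET, None, tpos))
                            tpos -= 1
                        steps.append((classify_pair(m[i - 1], t[tpos - 1]), i, tpos))
                        tpos -= 1
                    pairings.append(PairingMap(steps=tuple(steps)))
        for pairing in pairings:
            score = score_pairing(pairing, scheme)
            if score <= scheme.cutoff:
                start, e = pairing.transcript_range
                has_tb = any(s is PairState.BULGE_TARGET for s, _, _ in pairing.steps)
                bpos = next(
                    (i for i, (s, _, _) in enumerate(pairing.steps)
                     if s in (PairState.BULGE_MIRNA, PairState.BULGE_TARGET)),
                    -1,
                )
                key = (score, pairing.n_bulges, start, e, int(has_tb), bpos)
                candidates.append((key, pairing, score))
    candidates.sort(key=lambda c: c[0])
    kept, occupied = [], []
    for _key, pairing, score in candidates:
        start, e = pairing.transcript_range
        if any(start <= oe and os <= e for os, oe in occupied):
            continue
        kept.append((pairing.transcript_range, score, pairing.n_bulges))
        occupied.append((start, e))
    return sorted(kept)


# ---------------------------------------------------------------------------
# classify_pair and score_pairing


@pytest.mark.parametrize(
    "mirna_nt,target_nt,expected",
    [
        ("A", "U", PairState.MATCH),
        ("U", "A", PairState.MATCH),
        ("G", "C", PairState.MATCH),
        ("C", "G", PairState.MATCH),
        ("G", "U", PairState.GU),
        ("U", "G", PairState.GU),
        ("A", "G", PairState.MISMATCH),
        ("C", "U", PairState.MISMATCH),
        ("A", "N", PairState.MISMATCH),
    ],
)
def test_classify_pair(mirna_nt, target_nt, expected):
    assert classify_pair(mirna_nt, target_nt) is expected


class TestScorePairing:
    mirna = "UGACAGAAGAGAGUGAGCACA"  # 21 nt

    def _pairing(self, overrides):
        states = [PairState.MATCH] * 21
        for pos, st_ in overrides.items():
            states[pos - 1] = st_
        return ungapped_pairing(self.mirna, "N" * 40, 40, states=states)

    def test_perfect_complement_scores_zero(self):
        assert score_pairing(self._pairing({})) == 0.0

    def test_single_gu_outside_core(self):
        assert score_pairing(self._pairing({20: PairState.GU})) == 0.5

    def test_single_mismatch_in_core_doubles(self):
        assert score_pairing(self._pairing({5: PairState.MISMATCH})) == 2.0

    def test_gu_in_core_doubles(self):
        assert score_pairing(self._pairing({2: PairState.GU})) == 1.0

    @given(
        st.lists(
            st.sampled_from([PairState.MATCH, PairState.GU, PairState.MISMATCH]),
            min_size=19,
            max_size=24,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_per_position_oracle(self, states):
        pairing = ungapped_pairing("A" * len(states), "N" * 40, 40, states=states)
        assert score_pairing(pairing, DEFAULT_SCHEME) == oracle_score(pairing, DEFAULT_SCHEME)

    @given(
        st.lists(
            st.sampled_from([PairState.MATCH, PairState.GU, PairState.MISMATCH]),
            min_size=19,
            max_size=24,
        ),
        st.integers(min_value=1, max_value=19),
    )
    @settings(max_examples=100, derandomize=True)
    def test_adding_a_mispair_never_decreases_score(self, states, pos):
        pos = min(pos, len(states))
        base = ungapped_pairing("A" * len(states), "N" * 40, 40, states=states)
        worse_states = list(states)
        worse_states[pos - 1] = PairState.MISMATCH
        worse = ungapped_pairing("A" * len(states), "N" * 40, 40, states=worse_states)
        if states[pos - 1] is not PairState.MISMATCH:
            assert score_pairing(worse) >= score_pairing(base)


# ---------------------------------------------------------------------------
# expected_cleavage_position


@pytest.mark.parametrize(
    "length,end,expected",
    [(21, 1011, 1002), (20, 692, 683), (20, 20, 11)],
)
def test_cleavage_is_base_paired_to_mirna_10(length, end, expected):
    pairing = ungapped_pairing("A" * length, "N" * (end + 5), end)
    assert expected_cleavage_position(pairing) == expected


# ---------------------------------------------------------------------------
# find_sites


class TestFindSites:
    def test_exact_reverse_complement_gives_one_perfect_site(self):
        mirna = SequenceRecord(id="m", residues="UGACAGAAGAGAGUGAGCACA")
        flank5, flank3 = "CGAUCGAUCG", "GCUAGCUAGC"
        tx = SequenceRecord(id="t", residues=flank5 + reverse_complement(mirna.residues) + flank3)
        (site,) = find_sites(mirna, tx)
        assert (site.score, site.start, site.end) == (0.0, 11, 31)
        assert site.end - site.start + 1 == len(mirna)
        assert site.cleavage_position == site.end - 9

    def test_one_noncore_substitution_scores_one(self):
        mirna = SequenceRecord(id="m", residues="UGACAGAAGAGAGUGAGCACA")
        rc = list(reverse_complement(mirna.residues))
        # transcript base opposite miRNA position 15 is rc index L-15
        rc[len(rc) - 15] = mirna.residues[14]  # same base never pairs or wobbles
        tx = SequenceRecord(id="t", residues="CGAUCGAUCG" + "".join(rc) + "GCUAGCUAGC")
        (site,) = find_sites(mirna, tx)
        assert site.score == 1.0

    def test_score_invariant_under_transcript_context(self, small_transcriptome):
        mirna = syn.gen_mirnas(1, 21, seed=5)[0]
        edits = [(20, PairState.MISMATCH), (6, PairState.MISMATCH)]
        scores = []
        for tx in small_transcriptome[:3]:
            modified, truth, _ = syn.implant_site(tx, mirna, 50, edits=edits)
            sites = find_sites(mirna, modified)
            match = [s for s in sites if s.start == truth.start]
            assert len(match) == 1
            scores.append(match[0].score)
        assert len(set(scores)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_exhaustive_enumeration(self, seed):
        """Banded scan == brute force on random transcripts with planted sites."""
        rng = np.random.default_rng(seed)
        mirna = SequenceRecord(id="test-miR1", residues="UGACAGAAGAGAGUGAGCACA")
        tx = syn.gen_transcriptome(1, (300, 300), 0.45, seed=rng)[0]
        edit_pool = [(14, PairState.GU), (3, PairState.MISMATCH), (15, PairState.BULGE_TARGET)]
        n_edits = int(rng.integers(0, 3))
        tx, _, _ = syn.implant_site(tx, mirna, 100, edits=edit_pool[:n_edits])
        got = sorted(
            (( (s.start, s.end), s.score, s.n_bulges) for s in find_sites(mirna, tx))
        )
        assert got == oracle_enumerate_sites(mirna, tx, DEFAULT_SCHEME)

    def test_reported_range_lengths(self):
        mirna = syn.gen_mirnas(1, 21, seed=9)[0]
        for edits in ([], [(15, PairState.BULGE_TARGET)], [(15, PairState.BULGE_MIRNA)]):
            tx = syn.gen_transcriptome(1, (300, 300), 0.45, seed=13)[0]
            tx, truth, _ = syn.implant_site(tx, mirna, 120, edits=edits)
            for site in find_sites(mirna, tx):
                assert site.end - site.start + 1 in (20, 21, 22)

    def test_mirna_with_n_rejected(self):
        mirna = SequenceRecord(id="m", residues="NGACAGAAGAGAGUGAGCACA")
        tx = SequenceRecord(id="t", residues="ACGU" * 30)
        with pytest.raises(ValueError, match="contains N"):
            find_sites(mirna, tx)


# ---------------------------------------------------------------------------
# predict_targets


class TestPredictTargets:
    def test_empty_mirna_list_gives_empty_table(self, small_transcriptome):
        assert predict_targets([], small_transcriptome) == []

    def test_planted_perfect_site_gives_one_row(self, small_transcriptome):
        mirna = syn.gen_mirnas(1, 21, seed=3)[0]
        tx, truth, _ = syn.implant_site(small_transcriptome[0], mirna, 80)
        rows = predict_targets([mirna], [tx])
        assert len(rows) == 1
        assert rows[0].score == 0.0
        assert rows[0].cleavage_site == truth.cleavage_position

    def test_cutoff_excludes_high_penalty_sites(self):
        """Planted scores {0, 2, 3.5, 4.5}: only scores <= 4 are reported."""
        mirna = SequenceRecord(id="test-miR1", residues="UGACAGAAGAGAGUGAGCACA")
        base = syn.gen_transcriptome(4, (300, 300), 0.45, seed=8)
        edit_sets = {
            0.0: [],
            2.0: [(5, PairState.MISMATCH)],  # core mismatch, doubled
            3.5: [(5, PairState.MISMATCH), (20, PairState.MISMATCH), (14, PairState.GU)],
            4.5: [(5, PairState.MISMATCH), (6, PairState.MISMATCH), (15, PairState.GU)],
        }
        transcripts, truths = [], {}
        for tx, (score, edits) in zip(base, edit_sets.items()):
            modified, truth, _ = syn.implant_site(tx, mirna, 100, edits=edits)
            assert truth.expected_score == score
            transcripts.append(modified)
            truths[modified.id] = score
        rows = predict_targets([mirna], transcripts)
        reported = {r.transcript: r.score for r in rows}
        assert reported == {tid: sc for tid, sc in truths.items() if sc <= 4.0}

    def test_duplicate_ids_rejected(self, small_transcriptome):
        mirna = syn.gen_mirnas(1, 21, seed=3)[0]
        with pytest.raises(ValueError, match="duplicate"):
            predict_targets([mirna, mirna], small_transcriptome)


def test_mirna_family_extraction():
    assert mirna_family("osa-miR156l") == "miR156"
    assert mirna_family("aly-miR166a-5p") == "miR166"
    assert mirna_family("ptc-miR1450") == "miR1450"
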