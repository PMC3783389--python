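"""Seeded synthetic data with the statistical structure each stage assumes.

Every generator takes an integer seed and is bit-reproducible for a fixed
seed and parameter set.  Alongside its files each generator returns a truth
table so downstream stages can be checked for exact recovery: transcripts
carry planted target sites of controlled penalty score, degradome tags pile
up at the planted cleavage positions over a uniform Poisson background,
two-channel signals carry known log2 fold changes under log-normal
intensities and an optional intensity-dependent dye bias, and Ct tables
encode known expression ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import SequenceRecord, TagRecord, SignalRow, reverse_complement
from .target_prediction import (
    BULGE_FORBIDDEN_RANGE,
    DEFAULT_SCHEME,
    PairState,
    PairingMap,
    ScoringScheme,
    expected_cleavage_position,
    score_pairing,
)

_NT = np.array(list("ACGU"))


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def spawn_seeds(master_seed: int, n: int) -> list[np.random.Generator]:
    """Fan one master seed out into independent child streams.

    Children are spawned from ``SeedSequence(master_seed)`` in index order,
    so stage k always sees the same stream for a given master seed.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


# ---------------------------------------------------------------------------
# Transcriptomes and miRNAs


def gen_transcriptome(
    n: int,
    length_range: tuple[int, int] = (500, 1500),
    gc: float = 0.45,
    seed: int | np.random.Generator = 0,
) -> list[SequenceRecord]:
    """Generate i.i.d. random transcripts at a target GC content."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    lo, hi = length_range
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_NT, size=length, p=p))
        records.append(SequenceRecord(id=f"tx{i + 1:04d}", residues=seq))
    return records


def gen_mirnas(
    n: int, length: int = 21, seed: int | np.random.Generator = 0
) -> list[SequenceRecord]:
    """Generate random miRNA sequences of a fixed length."""
    rng = _rng(seed)
    return [
        SequenceRecord(id=f"sim-miR{i + 1:03d}", residues="".join(rng.choice(_NT, size=length)))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Target-site implantation

_MISMATCH_PARTNER = {"A": "A", "C": "C", "G": "G", "U": "U"}  # X:X never pairs or wobbles
_WOBBLE_PARTNER = {"G": "U", "U": "G"}


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for one implanted target site."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    expected_score: float
    cleavage_position: int


def implant_site(
    transcript: SequenceRecord,
    mirna: SequenceRecord,
    position: int,
    edits: Sequence[tuple[int, PairState]] = (),
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[SequenceRecord, PlantedSite, PairingMap]:
    """Write a target site for ``mirna`` into ``transcript`` at ``position``.

    The reverse complement of the miRNA is placed so the site starts at
    ``position`` (1-based), then ``edits`` — (miRNA position, state) pairs —
    are applied so the realized duplex has exactly the requested states:
    MISMATCH substitutes a non-pairing base, GU the wobble partner (miRNA
    base must be G or U), BULGE_MIRNA deletes the paired transcript base,
    BULGE_TARGET inserts an unpaired base 5' of the miRNA position's partner.
    Bulges opposite miRNA positions 9-12 are rejected.  Returns the modified
    transcript, the truth record (score from :func:`score_pairing`, cleavage
    from the slicer convention) and the realized pairing map.
    """
    m = mirna.residues
    L = len(m)
    edit_map = dict(edits)
    if len(edit_map) != len(edits):
        raise ValueError("at most one edit per miRNA position")
    n_bulges = sum(
        1 for s in edit_map.values() if s in (PairState.BULGE_MIRNA, PairState.BULGE_TARGET)
    )
    if n_bulges > scheme.max_bulges:
        raise ValueError(f"more than {scheme.max_bulges} bulge edit(s) requested")
    lo, hi = BULGE_FORBIDDEN_RANGE
    for pos, state in edit_map.items():
        if not 1 <= pos <= L:
            raise ValueError(f"edit position {pos} outside miRNA 1..{L}")
        if state in (PairState.BULGE_MIRNA, PairState.BULGE_TARGET) and lo <= pos <= hi:
            raise ValueError(f"bulge edits are disallowed opposite miRNA positions {lo}-{hi}")
        if state is PairState.BULGE_TARGET and pos == 1:
            raise ValueError("a transcript bulge must sit between two paired miRNA positions")
        if state is PairState.GU and m[pos - 1] not in _WOBBLE_PARTNER:
            raise ValueError(f"miRNA base {m[pos - 1]} at position {pos} cannot form G:U")

    # Build the site 5'->3' on the transcript: walk the miRNA 3'->5'.
    site_chars: list[str] = []
    states_3to5: list[tuple[PairState, int | None]] = []
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    for i in range(L, 0, -1):
        state = edit_map.get(i, PairState.MATCH)
        if state is PairState.BULGE_MIRNA:
            states_3to5.append((PairState.BULGE_MIRNA, i))
            continue
        if state is PairState.MATCH:
            site_chars.append(comp[m[i - 1]])
        elif state is PairState.MISMATCH:
            site_chars.append(_MISMATCH_PARTNER[m[i - 1]])
        elif state is PairState.GU:
            site_chars.append(_WOBBLE_PARTNER[m[i - 1]])
        else:  # BULGE_TARGET: unpaired base between the partners of i and i-1,
            # so its core-bookkeeping position (next paired miRNA nt) is i
            site_chars.append(comp[m[i - 1]])
            states_3to5.append((PairState.MATCH, i))
            site_chars.append("A")
            states_3to5.append((PairState.BULGE_TARGET, None))
            continue
        states_3to5.append((state, i))
    site = "".join(site_chars)
    span = len(site)
    t = transcript.residues
    if position < 1 or position + span - 1 > len(t):
        raise ValueError(
            f"site of span {span} at position {position} does not fit transcript "
            f"{transcript.id!r} (length {len(t)})"
        )
    modified = SequenceRecord(
        id=transcript.id,
        residues=t[: position - 1] + site + t[position + span - 1 :],
        description=transcript.description,
    )
    # Pairing map in miRNA 5'->3' order with absolute transcript coordinates.
    end = position + span - 1
    steps: list[tuple[PairState, int | None, int | None]] = []
    tpos = end
    for state, i in reversed(states_3to5):
        if state is PairState.BULGE_MIRNA:
            steps.append((state, i, None))
        else:
            steps.append((state, i, tpos))
            tpos -= 1
    pairing = PairingMap(steps=tuple(steps))
    truth = PlantedSite(
        mirna_id=mirna.id,
        transcript_id=transcript.id,
        start=position,
        end=end,
        expected_score=score_pairing(pairing, scheme),
        cleavage_position=expected_cleavage_position(pairing),
    )
    return modified, truth, pairing


# ---------------------------------------------------------------------------
# Degradome library


def sim_degradome(
    transcripts: Sequence[SequenceRecord],
    truth_sites: Sequence[PlantedSite],
    reads_per_site: int = 20,
    background_rate: float = 0.01,
    tag_length: int = 20,
    seed: int | np.random.Generator = 0,
) -> list[TagRecord]:
    """Emit degradome tags: planted pile-ups plus uniform background.

    Each truth site contributes a tag of ``tag_length`` whose 5' end sits at
    the site's expected cleavage position with abundance ``reads_per_site``.
    Each transcript additionally receives Poisson(background_rate * length)
    background tags at uniform positions, each of count 1.  Tags that would
    run past a transcript end are shortened and flagged as truncated.
    """
    if reads_per_site < 0 or background_rate < 0:
        raise ValueError("reads_per_site and background_rate must be >= 0")
    rng = _rng(seed)
    by_id = {tr.id: tr for tr in transcripts}
    tags: list[TagRecord] = []

    def emit(transcript: SequenceRecord, position: int, count: int) -> None:
        seq = transcript.residues[position - 1 : position - 1 + tag_length]
        tags.append(TagRecord(sequence=seq, count=count, truncated=len(seq) < tag_length))

    if reads_per_site > 0:
        for site in truth_sites:
            emit(by_id[site.transcript_id], site.cleavage_position, reads_per_site)
    for tr in transcripts:
        n_bg = int(rng.poisson(background_rate * len(tr.residues)))
        if n_bg:
            for pos in rng.integers(1, len(tr.residues) + 1, size=n_bg):
                emit(tr, int(pos), 1)
    return tags


# ---------------------------------------------------------------------------
# Two-channel microarray


@dataclass(frozen=True)
class ProbeTruth:
    probe_id: str
    mirna: str
    true_log2fc: float


def sim_microarray(
    n_probes: int = 500,
    n_diff: int = 50,
    log2fc: float = 2.0,
    noise_sd: float = 0.15,
    dye_bias: float | Callable[[np.ndarray], np.ndarray] | None = None,
    replicates: int = 3,
    bg_mean: float = 50.0,
    bg_sd: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SignalRow], list[ProbeTruth]]:
    """Simulate two-channel signals with known log2 fold changes.

    Base intensities are log-normal (log2 I ~ N(10, 1.5)).  The first
    ``n_diff`` probes carry a true fold change of +-``log2fc`` (alternating
    signs); channel B equals channel A times 2^fc, times 2^bias(A-value) if
    a dye bias is given (a constant log2 offset or a callable of the
    A-value), times per-spot log-normal noise of SD ``noise_sd`` (log2
    scale).  The background is an exact additive offset of ``bg_mean`` so
    noiseless settings reproduce the planted ratios exactly; ``bg_sd`` is
    reported as the background-SD statistic for the detectability filter.
    """
    if n_diff > n_probes:
        raise ValueError("n_diff must be <= n_probes")
    rng = _rng(seed)
    base_log2 = rng.normal(10.0, 1.5, size=n_probes)
    fcs = np.zeros(n_probes)
    fcs[:n_diff] = [log2fc if i % 2 == 0 else -log2fc for i in range(n_diff)]
    if dye_bias is None:
        bias_fn = lambda a: np.zeros_like(a)  # noqa: E731
    elif callable(dye_bias):
        bias_fn = dye_bias
    else:
        bias_fn = lambda a, c=float(dye_bias): np.full_like(a, c)  # noqa: E731
    rows: list[SignalRow] = []
    truth: list[ProbeTruth] = []
    for i in range(n_probes):
        probe_id = f"p{i + 1:04d}"
        mirna = f"sim-miR{i + 1:04d}"
        truth.append(ProbeTruth(probe_id=probe_id, mirna=mirna, true_log2fc=float(fcs[i])))
        for r in range(1, replicates + 1):
            eps_a = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            eps_b = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            la = base_log2[i] + eps_a
            lb0 = base_log2[i] + fcs[i] + eps_b
            av = 0.5 * (la + lb0)
            lb = lb0 + float(np.asarray(bias_fn(np.array([av])))[0])
            for channel, lv in (("A", la), ("B", lb)):
                rows.append(
                    SignalRow(
                        probe_id=probe_id,
                        mirna=mirna,
                        channel=channel,
                        replicate=r,
                        fg=float(2.0**lv + bg_mean),
                        bg_mean=bg_mean,
                        bg_sd=bg_sd,
                    )
                )
    return rows, truth


# ---------------------------------------------------------------------------
# qPCR


def sim_qpcr(
    true_ratios: Mapping[str, float],
    ct_ref: float = 20.0,
    noise_sd: float = 0.05,
    replicates: int = 3,
    seed: int | np.random.Generator = 0,
    reference_assay: str = "5.8S",
    test_sample: str = "test",
    calibrator_sample: str = "calibrator",
    dct_calibrator: float = 5.0,
) -> pd.DataFrame:
    """Simulate triplicate Ct values around known expression ratios.

    In the calibrator sample each target sits ``dct_calibrator`` cycles
    above the reference; in the test sample it is shifted by -log2(ratio).
    Gaussian noise of SD ``noise_sd`` cycles is added per Ct measurement.
    Returns a Ct table (sample, assay, experiment, ct).
    """
    if any(r <= 0 for r in true_ratios.values()):
        raise ValueError("true ratios must be > 0")
    rng = _rng(seed)

    def noisy(x: float) -> float:
        return float(x + rng.normal(0.0, noise_sd)) if noise_sd > 0 else float(x)

    rows = []
    for e in range(1, replicates + 1):
        for sample in (test_sample, calibrator_sample):
            rows.append({"sample": sample, "assay": reference_assay, "experiment": e, "ct": noisy(ct_ref)})
        for assay, ratio in true_ratios.items():
            rows.append(
                {
                    "sample": calibrator_sample,
                    "assay": assay,
                    "experiment": e,
                    "ct": noisy(ct_ref + dct_calibrator),
                }
            )
            rows.append(
                {
                    "sample": test_sample,
                    "assay": assay,
                    "experiment": e,
                    "ct": noisy(ct_ref + dct_calibrator - float(np.log2(ratio))),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "assay", "experiment", "ct"])
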