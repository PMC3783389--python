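"""Degradome (PARE) tag mapping, t-signatures, t-plots and target validation.

A degradome library sequences the 5' ends of uncapped, polyadenylated mRNA
fragments — the downstream products of miRNA-guided slicing.  Tags are
mapped exactly to transcripts; the per-position pile-up of tag 5' ends forms
a *t-plot*.  A predicted target site is validated when tags accumulate at
its expected cleavage position, and the supporting abundance is ranked
against the rest of the transcript:

* category I   — the site count equals the transcript-wide maximum;
* category II  — strictly between the median of occupied positions and the
  maximum;
* category III — at or below the median.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

from .formats import SequenceRecord, TagRecord


@dataclass(frozen=True)
class TagProfile:
    """Per-transcript counts of degradome tag 5' ends by 1-based position."""

    transcript_id: str
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty tag profile")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("profile counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_count(self) -> int:
        return max(self.counts.values())

    @property
    def median_count(self) -> float:
        """Median count over occupied positions."""
        return statistics.median(self.counts.values())


@dataclass(frozen=True)
class TSignature:
    """The transcript window around a mapped tag 5' end (15 nt each side)."""

    transcript_id: str
    position: int
    sequence: str
    left_truncated: bool
    right_truncated: bool


class SiteLike(Protocol):
    """Anything carrying a transcript id and an expected cleavage position."""

    transcript_id: str
    cleavage_position: int


@dataclass(frozen=True)
class CleavageEvent:
    """A degradome-supported target site with its abundance category."""

    site: SiteLike
    site_count: int
    transcript_max: int
    transcript_median: float
    category: str


def map_tags(
    tags: Iterable[TagRecord],
    transcripts: Sequence[SequenceRecord],
    min_length: int = 15,
) -> dict[str, TagProfile]:
    """Map tags exactly (full-length, sense strand) onto transcripts.

    Every occurrence of a tag in every transcript contributes the tag's full
    count at the occurrence's 5' position; multi-mapped tags are not split.
    Tags shorter than ``min_length`` (e.g. truncated at a transcript end)
    are too ambiguous to map and are skipped.  Transcripts with no hits are
    absent from the result.
    """
    tags = [t for t in tags if len(t.sequence) >= min_length]
    acc: dict[str, dict[int, int]] = {}
    for tr in transcripts:
        seq = tr.residues
        per_pos: dict[int, int] = {}
        for tag in tags:
            start = seq.find(tag.sequence)
            while start != -1:
                pos = start + 1  # 1-based 5' end
                per_pos[pos] = per_pos.get(pos, 0) + tag.count
                start = seq.find(tag.sequence, start + 1)
        if per_pos:
            acc[tr.id] = per_pos
    return {tid: TagProfile(transcript_id=tid, counts=dict(sorted(c.items()))) for tid, c in acc.items()}


def extract_t_signature(
    transcript: SequenceRecord, position: int, flank: int = 15
) -> TSignature:
    """Extract the (2*flank)-nt window around a tag 5' end.

    The untruncated window spans positions p-15 .. p+14, making the focal
    position the 16th nucleotide.  Windows hitting a transcript boundary are
    truncated and flagged.
    """
    L = len(transcript.residues)
    if not (1 <= position <= L):
        raise ValueError(f"position {position} outside transcript {transcript.id!r} (1..{L})")
    start = max(1, position - flank)
    end = min(L, position + flank - 1)
    return TSignature(
        transcript_id=transcript.id,
        position=position,
        sequence=transcript.residues[start - 1 : end],
        left_truncated=start > position - flank,
        right_truncated=end < position + flank - 1,
    )


def categorize(site_count: int, profile: TagProfile) -> str:
    """Assign the abundance category of a site count within a profile."""
    if site_count < 1:
        raise ValueError("site_count must be >= 1")
    if site_count == profile.max_count:
        return "I"
    if profile.median_count < site_count < profile.max_count:
        return "II"
    return "III"


def validate_targets(
    sites: Iterable[SiteLike],
    profiles: Mapping[str, TagProfile],
    min_reads: int = 1,
) -> list[CleavageEvent]:
    """Turn predicted sites with degradome support into cleavage events.

    A site yields an event when the tag count at its expected cleavage
    position reaches ``min_reads``; the event carries the transcript-wide
    maximum and median and the resulting category.  Input order is kept.
    """
    events = []
    for site in sites:
        profile = profiles.get(site.transcript_id)
        if profile is None:
            continue
        count = profile.counts.get(site.cleavage_position, 0)
        if count < min_reads:
            continue
        events.append(
            CleavageEvent(
                site=site,
                site_count=count,
                transcript_max=profile.max_count,
                transcript_median=profile.median_count,
                category=categorize(count, profile),
            )
        )
    return events


def t_plot_table(
    profile: TagProfile,
    marked_positions: Iterable[int] = (),
) -> list[tuple[int, int, bool]]:
    """Tabulate a t-plot: (position, count, marked) rows sorted by position.

    ``marked_positions`` flags candidate cleavage sites for plotting.
    """
    marked = set(marked_positions)
    return [(pos, count, pos in marked) for pos, count in sorted(profile.counts.items())]


def write_t_plot_table(
    profile: TagProfile, path, marked_positions: Iterable[int] = ()
) -> None:
    """Write a t-plot table as TSV (position, count, marked)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("position\tcount\tmarked\n")
        for pos, count, marked in t_plot_table(profile, marked_positions):
            fh.write(f"{pos}\t{count}\t{'yes' if marked else 'no'}\n")
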