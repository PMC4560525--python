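"""Aggregation-prone region (APR) calling and gatekeeper-flank annotation.

An APR is a maximal run of at least :data:`MIN_APR_LENGTH` consecutive
residues whose per-residue aggregation score exceeds
:data:`APR_SCORE_THRESHOLD` percent. The region score is the SUM of the
per-residue percent scores over the span, so the downstream "strong APR"
cut of 70 is reachable (a five-residue region averaging >14%/residue
crosses it); the summation convention is isolated in
:func:`region_score_from_track` so it can be swapped.

The three positions on either side of an APR are its gatekeeping flanks;
flank residues in {P, R, K, E, D} are gatekeepers. No distinction is made
between N- and C-terminal gatekeepers. Flanks are clipped at the sequence
termini rather than discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .datamodel import ProteinRecord, ScoreTrack, ValidationError

#: Per-residue percent score a residue must exceed to belong to an APR.
APR_SCORE_THRESHOLD = 5.0
#: Minimal APR length in residues.
MIN_APR_LENGTH = 5
#: Width of the gatekeeping flank on each side of an APR.
FLANK_WIDTH = 3
#: Residues counting as gatekeepers when found on a flank.
GATEKEEPER_RESIDUES = frozenset("PRKED")


@dataclass(frozen=True)
class APR:
    """One called aggregation-prone region (1-based inclusive span)."""

    protein_id: str
    start: int
    end: int
    region_score: float
    flank_positions: tuple[int, ...] = ()
    gatekeeper_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < MIN_APR_LENGTH:
            raise ValidationError(
                f"APR {self.protein_id}:{self.start}-{self.end} shorter "
                f"than {MIN_APR_LENGTH}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def overlaps(self, other: "APR") -> bool:
        return self.start <= other.end and other.start <= self.end


def region_score_from_track(track: ScoreTrack, start: int, end: int) -> float:
    """Region score of an inclusive span: sum of per-residue percent scores."""
    return float(np.sum(track.scores[start - 1 : end]))


def _flanks(start: int, end: int, length: int) -> tuple[int, ...]:
    left = range(max(1, start - FLANK_WIDTH), start)
    right = range(end + 1, min(length, end + FLANK_WIDTH) + 1)
    return tuple(left) + tuple(right)


def call_aprs(track: ScoreTrack) -> list[APR]:
    """Call all APRs of one track, ordered by start position.

    Returns the maximal runs of scores > 5 with length >= 5; runs are
    non-overlapping by construction and extending any of them by one
    residue would violate the threshold or the track bounds.
    """
    above = track.scores > APR_SCORE_THRESHOLD
    L = len(above)
    aprs: list[APR] = []
    i = 0
    while i < L:
        if above[i]:
            j = i
            while j + 1 < L and above[j + 1]:
                j += 1
            if j - i + 1 >= MIN_APR_LENGTH:
                start, end = i + 1, j + 1
                aprs.append(
                    APR(
                        protein_id=track.protein_id,
                        start=start,
                        end=end,
                        region_score=region_score_from_track(track, start, end),
                        flank_positions=_flanks(start, end, L),
                    )
                )
            i = j + 1
        else:
            i += 1
    return aprs


def annotate_gatekeepers(apr: APR, sequence: str | ProteinRecord) -> APR:
    """Fill in the gatekeeper positions among an APR's flank positions."""
    seq = sequence.sequence if isinstance(sequence, ProteinRecord) else sequence
    flanks = apr.flank_positions or _flanks(apr.start, apr.end, len(seq))
    gatekeepers = tuple(
        p for p in flanks if seq[p - 1] in GATEKEEPER_RESIDUES
    )
    return replace(apr, flank_positions=flanks, gatekeeper_positions=gatekeepers)


def call_and_annotate(track: ScoreTrack, protein: ProteinRecord) -> list[APR]:
    """Call APRs and annotate their gatekeeper flanks in one pass."""
    if len(track) != protein.length:
        raise ValidationError(
            f"track length {len(track)} != protein length {protein.length} "
            f"for {protein.protein_id}"
        )
    return [annotate_gatekeepers(a, protein) for a in call_aprs(track)]


def residue_fraction_percent(n_apr_residues: int, n_total: int) -> float:
    """APR-residue count over total residue count, as a percentage."""
    if n_total <= 0:
        raise ValidationError("total residue count must be positive")
    return 100.0 * n_apr_residues / n_total


def apr_residue_fraction(tracks: Iterable[ScoreTrack]) -> float:
    """Percent of residues lying inside any called APR, over a protein set."""
    n_apr = 0
    n_total = 0
    for track in tracks:
        n_total += len(track)
        n_apr += sum(a.length for a in call_aprs(track))
    if n_total == 0:
        raise ValidationError("apr_residue_fraction requires at least one track")
    return residue_fraction_percent(n_apr, n_total)


def strongest_apr(aprs: Sequence[APR]) -> float:
    """Maximal region score in a list of APRs; 0 when the list is empty."""
    return max((a.region_score for a in aprs), default=0.0)
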