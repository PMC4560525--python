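"""Mapping of variants and APRs onto structural domains.

An APR is assigned to every domain with which it shares at least one
residue; an APR straddling a boundary therefore contributes its full region
score to both domains (no pro-rating — the convention is isolated here).
A variant belongs to the unique domain covering its position, or to none
(inter-domain "linker" variants), in which case it is excluded from
domain-level denominators downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .aprs import APR, strongest_apr
from .datamodel import DomainAnnotation, ScoreTrack, ValidationError, Variant


@dataclass(frozen=True)
class DomainAggregationSignature:
    """Per-domain aggregation signature.

    normalized_score: total per-residue track score over the domain divided
    by domain length (percent units); n_aprs: number of APRs assigned to the
    domain; strongest_apr_score: maximal region score among them (0 if none).
    """

    protein_id: str
    domain_id: str
    normalized_score: float
    n_aprs: int
    strongest_apr_score: float

    def __post_init__(self) -> None:
        if self.normalized_score < 0 or self.n_aprs < 0:
            raise ValidationError("signature fields must be non-negative")
        if (self.n_aprs == 0) != (self.strongest_apr_score == 0):
            raise ValidationError(
                "strongest_apr_score must be 0 exactly when n_aprs is 0"
            )


def assign_apr_to_domains(
    apr: APR, domains: Iterable[DomainAnnotation]
) -> list[str]:
    """Ids of all domains sharing at least one residue with the APR span."""
    return [
        d.domain_id
        for d in domains
        if d.protein_id == apr.protein_id
        and d.start <= apr.end
        and apr.start <= d.end
    ]


def assign_variant_domain(
    variant: Variant, domains: Iterable[DomainAnnotation]
) -> str | None:
    """The unique domain covering the variant position, or None (linker)."""
    for d in domains:
        if d.protein_id == variant.protein_id and d.contains(variant.position):
            return d.domain_id
    return None


def domain_signature(
    domain: DomainAnnotation,
    track: ScoreTrack,
    aprs: Sequence[APR],
) -> DomainAggregationSignature:
    """Compute the aggregation signature of one domain."""
    if len(track) < domain.end:
        raise ValidationError(
            f"track for {domain.protein_id} does not cover domain "
            f"{domain.domain_id} (end {domain.end})"
        )
    total = float(np.sum(track.scores[domain.start - 1 : domain.end]))
    assigned = [a for a in aprs if domain.domain_id in assign_apr_to_domains(a, [domain])]
    return DomainAggregationSignature(
        protein_id=domain.protein_id,
        domain_id=domain.domain_id,
        normalized_score=total / domain.length,
        n_aprs=len(assigned),
        strongest_apr_score=strongest_apr(assigned),
    )


def signatures_for_proteins(
    domains: Iterable[DomainAnnotation],
    tracks: dict[str, ScoreTrack],
    aprs_by_protein: dict[str, Sequence[APR]],
) -> dict[tuple[str, str], DomainAggregationSignature]:
    """Signatures for every domain, keyed by (protein_id, domain_id)."""
    out: dict[tuple[str, str], DomainAggregationSignature] = {}
    for d in domains:
        track = tracks.get(d.protein_id)
        if track is None:
            raise ValidationError(f"no track for protein {d.protein_id}")
        sig = domain_signature(d, track, aprs_by_protein.get(d.protein_id, ()))
        out[(d.protein_id, d.domain_id)] = sig
    return out
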