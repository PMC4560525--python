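"""Per-variant classification: intrinsic aggregation effect, stability
class, disorder flag, domain signature and the combined
"aggregation-increasing" rule.

Intrinsic taxonomy (precedence DE_NOVO_APR > IN_APR > GATEKEEPER > OUTSIDE):

* DE_NOVO_APR — the mutant track contains an APR sharing no position with
  any wild-type APR; a variant that both creates a new APR and sits inside
  an existing one counts as de novo, since de-novo creation is reported as
  a separate, additive category.
* IN_APR — the variant position lies inside a wild-type APR (wild-type
  boundaries are authoritative).
* GATEKEEPER — the position is a wild-type gatekeeper: a flank position
  (within 3 of an APR) occupied by one of {P, R, K, E, D}.
* OUTSIDE — anything else.

The direction of change comes from the sign of ``delta_score`` (mutant
total APR region score minus wild-type total, percent-sum units); values
within a tolerance (default 1.0) are NEUTRAL, which absorbs float noise
from rescoring. A de-novo APR always counts as INCREASE.

The combined rule flags a variant as aggregation-increasing when
ddG >= 2 kcal/mol AND the strongest APR of the variant's (wild-type)
structural domain exceeds a region score of 70 — destabilization plausibly
exposing a strong, normally buried APR. Variants without a ddG value or
without a covering domain get an NA verdict, distinct from False, and are
excluded from rule denominators.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .aprs import (
    APR,
    GATEKEEPER_RESIDUES,
    call_and_annotate,
    call_aprs,
    strongest_apr,
)
from .datamodel import (
    DisorderTrack,
    DomainAnnotation,
    ProteinRecord,
    ScoreTrack,
    StabilityRecord,
    ValidationError,
    Variant,
)
from .domains import (
    DomainAggregationSignature,
    assign_variant_domain,
    signatures_for_proteins,
)
from .scoring import DEFAULT_SCORER, ScorerConfig, mutate_and_rescore, score_sequence


class IntrinsicCategory(str, enum.Enum):
    IN_APR = "IN_APR"
    GATEKEEPER = "GATEKEEPER"
    DE_NOVO_APR = "DE_NOVO_APR"
    OUTSIDE = "OUTSIDE"


class Direction(str, enum.Enum):
    INCREASE = "INCREASE"
    DECREASE = "DECREASE"
    NEUTRAL = "NEUTRAL"


class StabilityClass(str, enum.Enum):
    STABILIZING = "stabilizing"
    NEUTRAL = "neutral"
    DESTABILIZING = "destabilizing"
    STRONGLY_DESTABILIZING = "strongly_destabilizing"


#: ddG above which a mutation is destabilizing (kcal/mol).
DDG_DESTABILIZING = 0.5
#: ddG below which a mutation is stabilizing (kcal/mol).
DDG_STABILIZING = -0.5
#: ddG at or above which a mutation is strongly destabilizing (kcal/mol).
DDG_STRONG = 2.0
#: Domain strongest-APR region score above which an APR counts as strong.
STRONG_APR_SCORE = 70.0


def classify_stability(ddg: float) -> StabilityClass:
    """Bucket a ddG value; the strong cut (>= 2) refines "destabilizing"."""
    if ddg >= DDG_STRONG:
        return StabilityClass.STRONGLY_DESTABILIZING
    if ddg > DDG_DESTABILIZING:
        return StabilityClass.DESTABILIZING
    if ddg < DDG_STABILIZING:
        return StabilityClass.STABILIZING
    return StabilityClass.NEUTRAL


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds of the combined rule and auxiliary classifiers."""

    ddg_min: float = DDG_STRONG
    apr_min: float = STRONG_APR_SCORE
    epsilon: float = 1.0  # percent-sum tolerance below which delta is NEUTRAL
    disorder_cutoff: float = 0.5  # inclusive


DEFAULT_CLASSIFY = ClassifyConfig()

_CONFIG_KEYS = {
    "rule.ddg_min": ("ddg_min", float),
    "rule.apr_min": ("apr_min", float),
    "rule.epsilon": ("epsilon", float),
    "disorder.cutoff": ("disorder_cutoff", float),
}


def classify_config_from_mapping(mapping: Mapping[str, str]) -> ClassifyConfig:
    kwargs = {}
    for key, (fieldname, cast) in _CONFIG_KEYS.items():
        if key in mapping:
            kwargs[fieldname] = cast(mapping[key])
    return replace(DEFAULT_CLASSIFY, **kwargs) if kwargs else DEFAULT_CLASSIFY


@dataclass(frozen=True)
class IntrinsicEffect:
    category: IntrinsicCategory
    direction: Direction
    delta_score: float


def classify_intrinsic(
    wt_aprs: Sequence[APR],
    mut_aprs: Sequence[APR],
    wt_track: ScoreTrack,
    mut_track: ScoreTrack,
    variant: Variant,
    tolerance: float = DEFAULT_CLASSIFY.epsilon,
) -> IntrinsicEffect:
    """Classify the variant's effect on intrinsic aggregation propensity.

    ``wt_aprs`` must carry gatekeeper annotation (see
    :func:`aggrevar.aprs.annotate_gatekeepers`) for the GATEKEEPER test.
    """
    if len(wt_track) != len(mut_track):
        raise ValidationError("wild-type and mutant tracks differ in length")

    delta = sum(a.region_score for a in mut_aprs) - sum(
        a.region_score for a in wt_aprs
    )
    de_novo = any(
        not any(m.overlaps(w) for w in wt_aprs) for m in mut_aprs
    )
    if de_novo:
        # a genuinely new APR always adds propensity
        return IntrinsicEffect(IntrinsicCategory.DE_NOVO_APR, Direction.INCREASE, delta)

    if abs(delta) <= tolerance:
        direction = Direction.NEUTRAL
    elif delta > 0:
        direction = Direction.INCREASE
    else:
        direction = Direction.DECREASE

    if any(a.contains(variant.position) for a in wt_aprs):
        return IntrinsicEffect(IntrinsicCategory.IN_APR, direction, delta)
    if any(
        variant.position in a.gatekeeper_positions
        and variant.wt_aa in GATEKEEPER_RESIDUES
        for a in wt_aprs
    ):
        return IntrinsicEffect(IntrinsicCategory.GATEKEEPER, direction, delta)
    return IntrinsicEffect(IntrinsicCategory.OUTSIDE, direction, delta)


def is_aggregation_increasing(
    ddg: float | None,
    domain_strongest_apr: float | None,
    config: ClassifyConfig = DEFAULT_CLASSIFY,
) -> bool | None:
    """Combined rule: ddG >= 2 (inclusive) and strongest domain APR > 70
    (strict). Returns None (NA) when either input is unavailable."""
    if ddg is None or domain_strongest_apr is None:
        return None
    return ddg >= config.ddg_min and domain_strongest_apr > config.apr_min


def classify_disorder(
    variant: Variant,
    disorder_track: DisorderTrack | None,
    cutoff: float = DEFAULT_CLASSIFY.disorder_cutoff,
) -> bool | None:
    """True iff the disorder score at the variant position is >= cutoff
    (inclusive). None (NA) when no track is available."""
    if disorder_track is None:
        return None
    if variant.position > len(disorder_track):
        raise ValidationError(
            f"disorder track for {variant.protein_id} does not cover "
            f"position {variant.position}"
        )
    return bool(disorder_track.scores[variant.position - 1] >= cutoff)


@dataclass(frozen=True)
class VariantClassification:
    """The full per-variant verdict."""

    variant: Variant
    intrinsic: IntrinsicEffect
    ddg: float | None
    stability_class: StabilityClass | None
    disordered: bool | None
    domain_id: str | None
    domain_strongest_apr: float | None
    aggregation_increasing: bool | None

    def as_row(self) -> dict:
        v = self.variant
        return {
            "protein_id": v.protein_id,
            "position": v.position,
            "wt_aa": v.wt_aa,
            "mut_aa": v.mut_aa,
            "label": v.label,
            "intrinsic_category": self.intrinsic.category.value,
            "intrinsic_direction": self.intrinsic.direction.value,
            "delta_score": self.intrinsic.delta_score,
            "ddg": self.ddg,
            "stability_class": (
                self.stability_class.value if self.stability_class else None
            ),
            "disordered": self.disordered,
            "domain_id": self.domain_id,
            "domain_strongest_apr": self.domain_strongest_apr,
            "aggregation_increasing": self.aggregation_increasing,
        }


def _frac(flags: list[bool]) -> float | None:
    return (sum(flags) / len(flags)) if flags else None


def summarize_cohorts(
    classifications: Sequence[VariantClassification],
) -> dict:
    """Per-cohort summary fractions, recomputable from the per-variant rows.

    NA-flagged records are excluded from the denominators of the flags they
    are NA for, and counted in the exclusion tallies.
    """
    summary: dict = {}
    labels = sorted({c.variant.label for c in classifications})
    for label in labels:
        sub = [c for c in classifications if c.variant.label == label]
        cat = [c.intrinsic.category for c in sub]
        agg = [c.aggregation_increasing for c in sub if c.aggregation_increasing is not None]
        dis = [c.disordered for c in sub if c.disordered is not None]
        ddg = [c for c in sub if c.ddg is not None]
        summary[label] = {
            "n": len(sub),
            "frac_in_apr": _frac([c == IntrinsicCategory.IN_APR for c in cat]),
            "frac_gatekeeper": _frac([c == IntrinsicCategory.GATEKEEPER for c in cat]),
            "frac_de_novo": _frac([c == IntrinsicCategory.DE_NOVO_APR for c in cat]),
            "frac_intrinsic_increase": _frac(
                [c.intrinsic.direction == Direction.INCREASE for c in sub]
            ),
            "frac_disordered": _frac([bool(d) for d in dis]),
            "frac_strongly_destabilizing": _frac(
                [
                    c.stability_class == StabilityClass.STRONGLY_DESTABILIZING
                    for c in ddg
                ]
            )
            if ddg
            else None,
            "frac_aggregation_increasing": _frac([bool(a) for a in agg]),
            "n_rule_denominator": len(agg),
            "n_excluded_no_ddg": sum(1 for c in sub if c.ddg is None),
            "n_excluded_no_domain": sum(1 for c in sub if c.domain_id is None),
        }
    return summary


def classify_cohort(
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    variants: Sequence[Variant],
    ddgs: Iterable[StabilityRecord] = (),
    domains: Sequence[DomainAnnotation] = (),
    tracks: Mapping[str, ScoreTrack] | None = None,
    disorder: Mapping[str, DisorderTrack] | None = None,
    signatures: Mapping[tuple[str, str], DomainAggregationSignature] | None = None,
    scorer: ScorerConfig = DEFAULT_SCORER,
    config: ClassifyConfig = DEFAULT_CLASSIFY,
) -> tuple[list[VariantClassification], dict]:
    """Classify every variant and summarize per cohort.

    Wild-type tracks are computed with the stand-in scorer when not
    supplied; mutant tracks are always computed with the scorer (externally
    supplied tracks cannot be re-derived for arbitrary mutants). Unresolvable
    inputs (missing ddG, linker variants) yield NA fields, never silently
    dropped rows; the summary reports the exclusion counts.

    Returns (classifications, run summary).
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.protein_id: p for p in proteins}
    for v in variants:
        if v.protein_id not in proteins:
            raise ValidationError(f"variant on unknown protein {v.protein_id}")
        v.check_against(proteins[v.protein_id])

    needed = {v.protein_id for v in variants}
    if tracks is None:
        tracks = {pid: score_sequence(proteins[pid], scorer) for pid in needed}
    wt_aprs = {
        pid: call_and_annotate(tracks[pid], proteins[pid]) for pid in needed
    }
    domains_by_protein: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        domains_by_protein.setdefault(d.protein_id, []).append(d)
    if signatures is None:
        signatures = signatures_for_proteins(
            [d for d in domains if d.protein_id in tracks], tracks, wt_aprs
        )
    ddg_map = {r.key: r.ddg for r in ddgs}

    out: list[VariantClassification] = []
    for v in variants:
        protein = proteins[v.protein_id]
        _, mut_track = mutate_and_rescore(protein, v, scorer)
        mut_aprs = call_aprs(mut_track)
        # when the WT track is external the intrinsic delta still compares
        # scorer-derived WT vs mutant APRs for scale consistency
        wt_track = tracks[v.protein_id]
        intrinsic = classify_intrinsic(
            wt_aprs[v.protein_id], mut_aprs, wt_track, mut_track, v, config.epsilon
        )
        ddg = ddg_map.get(v.key)
        domain_id = assign_variant_domain(v, domains_by_protein.get(v.protein_id, ()))
        sig = signatures.get((v.protein_id, domain_id)) if domain_id else None
        strongest = sig.strongest_apr_score if sig is not None else None
        out.append(
            VariantClassification(
                variant=v,
                intrinsic=intrinsic,
                ddg=ddg,
                stability_class=classify_stability(ddg) if ddg is not None else None,
                disordered=classify_disorder(
                    v, (disorder or {}).get(v.protein_id), config.disorder_cutoff
                ),
                domain_id=domain_id,
                domain_strongest_apr=strongest,
                aggregation_increasing=is_aggregation_increasing(
                    ddg, strongest, config
                ),
            )
        )

    summary = {
        "thresholds": {
            "ddg_min": config.ddg_min,
            "apr_min": config.apr_min,
            "epsilon": config.epsilon,
            "disorder_cutoff": config.disorder_cutoff,
        },
        "n_variants": len(out),
        "cohorts": summarize_cohorts(out),
    }
    return out, summary
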