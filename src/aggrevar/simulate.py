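"""Synthetic proteome / variant-cohort generator.

Generates self-contained datasets — protein sequences, aggregation and
disorder tracks, domain annotations, labeled variant cohorts and per-variant
ddG values — with planted pathogenic/neutral contrasts:

* a configurable fraction of each cohort satisfies the combined
  "aggregation-increasing" condition (variant inside a domain whose
  strongest APR region score exceeds 70, with ddG >= 2 kcal/mol);
* cohorts differ in the fraction of variants hitting APRs, gatekeeper
  flanks and disordered positions;
* pathogenic ddG values are drawn from a mixture shifted toward
  destabilizing values.

Sequences are sampled residue-by-residue from a background distribution
with hydrophobic residues down-weighted (so spontaneous APRs are rare),
then APR cores are written in as hydrophobic (strong) or mildly
aggregation-prone (weak) stretches and flanks optionally overwritten with
gatekeeper residues. Tracks are then computed by the stand-in scorer, so
sequences and tracks are always mutually consistent, and APRs are re-called
on the generated tracks: a protein is resampled until every planted region
verifiably satisfies its strong (>70) or weak (<=70) intent at the domain
level. Ground-truth flags are recorded from the realized data, never from
the sampling intent alone.

All randomness flows from a single integer seed through one
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .aprs import APR, GATEKEEPER_RESIDUES, call_and_annotate, strongest_apr
from .classify import STRONG_APR_SCORE, DDG_STRONG
from .datamodel import (
    DisorderTrack,
    DomainAnnotation,
    ProteinRecord,
    ScoreTrack,
    StabilityRecord,
    ValidationError,
    Variant,
    write_ddg_table,
    write_domain_table,
    write_fasta,
    write_track,
    write_variant_table,
)
from .scoring import DEFAULT_SCORER, ScorerConfig, score_sequence

# Background residue frequencies: natural composition with the strongly
# hydrophobic / beta-prone residues down-weighted so that spontaneous APRs
# are rare and planted regions dominate the signal.
_BACKGROUND_FREQS = {
    "A": 0.07, "R": 0.06, "N": 0.05, "D": 0.06, "C": 0.01, "Q": 0.05,
    "E": 0.08, "G": 0.08, "H": 0.03, "I": 0.02, "L": 0.04, "K": 0.07,
    "M": 0.01, "F": 0.02, "P": 0.06, "S": 0.09, "T": 0.07, "W": 0.01,
    "Y": 0.02, "V": 0.02,
}
_BG_AAS = np.array(list(_BACKGROUND_FREQS))
_BG_P = np.array(list(_BACKGROUND_FREQS.values()))
_BG_P = _BG_P / _BG_P.sum()

_STRONG_CORE_AAS = np.array(list("IVLF"))
# Mildly aggregation-prone 5-mers whose called region score stays <= 70
# in a neutral context (verified by re-calling after generation).
_WEAK_CORE_TEMPLATES = ("AVAVA", "AVTVA", "TVTVT", "AVSVA")

_ALL_AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_GK_AAS = np.array(sorted(GATEKEEPER_RESIDUES))
_NEUTRAL_AAS = np.array(list("SGNT"))


@dataclass(frozen=True)
class CohortSpec:
    """Per-cohort knobs: size, planted prevalence, site mix, ddG mixture."""

    n: int
    #: fraction of the cohort planted to satisfy the combined rule
    prevalence: float
    #: probability that a variant is placed inside an APR
    p_apr_site: float
    #: probability that a variant is placed on a gatekeeper flank residue
    p_gatekeeper_site: float
    #: probability that a variant is placed on a disordered position
    p_disorder_site: float
    #: ddG mixture for non-planted variants: (weight, mean, sd) components
    ddg_mixture: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        probs = (self.prevalence, self.p_apr_site, self.p_gatekeeper_site,
                 self.p_disorder_site)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must be in [0, 1]")
        if self.p_apr_site + self.p_gatekeeper_site + self.p_disorder_site > 1.0:
            raise ValidationError("site-category probabilities exceed 1")
        w = sum(c[0] for c in self.ddg_mixture)
        if not self.ddg_mixture or abs(w - 1.0) > 1e-9:
            raise ValidationError("ddG mixture weights must sum to 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; defaults define the study conditions.

    Cohort sizes and planted prevalences default to 5000 pathogenic /
    1000 neutral with aggregation-increasing prevalences 0.225 / 0.075,
    site-category mixes of 15.4%/12% (pathogenic) and 11.3%/8% (neutral)
    for APR/gatekeeper hits, disorder-site probabilities 0.12 / 0.24, and
    a pathogenic ddG mixture 0.6 N(3.0, 1.5) + 0.4 N(0.5, 1.0) versus
    neutral N(0.3, 1.0) (kcal/mol). Planted variants draw ddG from
    N(3.5, 1.0) truncated at 2.
    """

    seed: int = 0
    n_proteins: int = 60
    length_range: tuple[int, int] = (200, 400)
    domains_per_protein: tuple[int, int] = (2, 4)
    domain_length_range: tuple[int, int] = (60, 120)
    linker_length_range: tuple[int, int] = (10, 30)
    p_strong_apr: float = 0.35
    p_weak_apr: float = 0.35
    strong_apr_length_range: tuple[int, int] = (6, 9)
    gatekeeper_prob: float = 0.5
    disorder_segment_prob: float = 0.6
    disorder_segment_length_range: tuple[int, int] = (20, 40)
    pathogenic: CohortSpec = CohortSpec(
        n=5000,
        prevalence=0.225,
        p_apr_site=0.154,
        p_gatekeeper_site=0.12,
        p_disorder_site=0.12,
        ddg_mixture=((0.6, 3.0, 1.5), (0.4, 0.5, 1.0)),
    )
    neutral: CohortSpec = CohortSpec(
        n=1000,
        prevalence=0.075,
        p_apr_site=0.113,
        p_gatekeeper_site=0.08,
        p_disorder_site=0.24,
        ddg_mixture=((1.0, 0.3, 1.0),),
    )
    planted_ddg_mean: float = 3.5
    planted_ddg_sd: float = 1.0
    #: shift (kcal/mol per unit of strongest-APR/70) correlating non-planted
    #: ddG with domain APR strength; 0 = independence
    ddg_apr_correlation: float = 0.0
    scorer: ScorerConfig = DEFAULT_SCORER
    max_protein_retries: int = 80

    def __post_init__(self) -> None:
        for lo, hi in (
            self.length_range, self.domains_per_protein,
            self.domain_length_range, self.linker_length_range,
            self.strong_apr_length_range, self.disorder_segment_length_range,
        ):
            if lo > hi or lo < 1:
                raise ValidationError(f"bad range ({lo}, {hi})")
        if self.strong_apr_length_range[1] + 8 > self.domain_length_range[0]:
            raise ValidationError(
                "APR cores must fit inside the smallest domain with margin"
            )
        for p in (self.p_strong_apr, self.p_weak_apr, self.gatekeeper_prob,
                  self.disorder_segment_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted condition flags for one variant, recorded from realized data."""

    variant: Variant
    aggregation_increasing: bool
    site_category: str  # in_apr | gatekeeper | other
    disordered_site: bool
    in_strong_domain: bool


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    proteins: list[ProteinRecord]
    tracks: dict[str, ScoreTrack]
    disorder: dict[str, DisorderTrack]
    domains: list[DomainAnnotation]
    variants: list[Variant]
    ddgs: list[StabilityRecord]
    ground_truth: list[GroundTruth]

    @property
    def protein_map(self) -> dict[str, ProteinRecord]:
        return {p.protein_id: p for p in self.proteins}

    def write(self, directory: str | Path) -> None:
        """Write the dataset as FASTA + TSVs plus a ground-truth TSV."""
        import pandas as pd

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, d / "proteins.fasta")
        write_track(self.tracks.values(), d / "aggregation_track.tsv")
        write_track(self.disorder.values(), d / "disorder_track.tsv")
        write_domain_table(self.domains, d / "domains.tsv")
        write_variant_table(self.variants, d / "variants.tsv")
        write_ddg_table(self.ddgs, d / "ddg.tsv")
        pd.DataFrame(
            [
                {
                    "protein_id": g.variant.protein_id,
                    "position": g.variant.position,
                    "wt_aa": g.variant.wt_aa,
                    "mut_aa": g.variant.mut_aa,
                    "label": g.variant.label,
                    "aggregation_increasing": g.aggregation_increasing,
                    "site_category": g.site_category,
                    "disordered_site": g.disordered_site,
                    "in_strong_domain": g.in_strong_domain,
                }
                for g in self.ground_truth
            ]
        ).to_csv(d / "ground_truth.tsv", sep="\t", index=False)


@dataclass
class _DomainInfo:
    annotation: DomainAnnotation
    intent: str  # strong | weak | none
    strongest: float = 0.0
    apr_positions: list[int] = field(default_factory=list)
    gatekeeper_positions: list[int] = field(default_factory=list)
    disorder_positions: list[int] = field(default_factory=list)
    other_positions: list[int] = field(default_factory=list)


def _sample_layout(cfg: SyntheticConfig, rng: np.random.Generator, L: int):
    """Tile a protein with alternating linkers and domains."""
    n_target = rng.integers(cfg.domains_per_protein[0],
                            cfg.domains_per_protein[1] + 1)
    spans = []
    pos = 1 + rng.integers(cfg.linker_length_range[0],
                           cfg.linker_length_range[1] + 1)
    while len(spans) < n_target:
        dlen = rng.integers(cfg.domain_length_range[0],
                            cfg.domain_length_range[1] + 1)
        if pos + dlen - 1 > L:
            break
        spans.append((int(pos), int(pos + dlen - 1)))
        pos += dlen + rng.integers(cfg.linker_length_range[0],
                                   cfg.linker_length_range[1] + 1)
    return spans


def _generate_protein(
    cfg: SyntheticConfig, rng: np.random.Generator, pid: str
):
    """Sample one protein until its called APRs match the planted intent."""
    for _ in range(cfg.max_protein_retries):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        spans = _sample_layout(cfg, rng, L)
        if not spans:
            continue
        seq = rng.choice(_BG_AAS, size=L, p=_BG_P)
        intents = []
        for (start, end) in spans:
            u = rng.random()
            intent = (
                "strong" if u < cfg.p_strong_apr
                else "weak" if u < cfg.p_strong_apr + cfg.p_weak_apr
                else "none"
            )
            intents.append(intent)
            if intent == "none":
                continue
            if intent == "strong":
                clen = int(rng.integers(cfg.strong_apr_length_range[0],
                                        cfg.strong_apr_length_range[1] + 1))
                core = rng.choice(_STRONG_CORE_AAS, size=clen)
            else:
                core = np.array(
                    list(_WEAK_CORE_TEMPLATES[rng.integers(len(_WEAK_CORE_TEMPLATES))])
                )
                clen = len(core)
            # keep a >= 4 residue margin so flanks stay inside the domain
            cstart = int(rng.integers(start + 4, end - clen - 2))
            seq[cstart - 1 : cstart - 1 + clen] = core
            flank = list(range(cstart - 3, cstart)) + list(
                range(cstart + clen, cstart + clen + 3)
            )
            if intent == "strong":
                # charged/proline gatekeepers survive next to a strong core
                for p in flank:
                    if start <= p <= end and rng.random() < cfg.gatekeeper_prob:
                        seq[p - 1] = rng.choice(_GK_AAS)
            else:
                # a charged flank would suppress a weak core below the APR
                # call threshold, so weak cores get a neutral context
                for p in flank:
                    if start <= p <= end:
                        seq[p - 1] = rng.choice(_NEUTRAL_AAS)

        protein = ProteinRecord(pid, "".join(seq))
        track = score_sequence(protein, cfg.scorer)
        aprs = call_and_annotate(track, protein)

        infos = []
        ok = True
        for (start, end), intent in zip(spans, intents):
            dom = DomainAnnotation(pid, f"{pid}_d{len(infos) + 1}", start, end)
            assigned = [a for a in aprs if a.start <= end and start <= a.end]
            strongest = strongest_apr(assigned)
            if intent == "strong" and strongest <= STRONG_APR_SCORE:
                ok = False
                break
            if intent != "strong" and strongest > STRONG_APR_SCORE:
                ok = False
                break
            if intent == "weak" and not assigned:
                ok = False
                break
            apr_pos = [
                p for a in assigned for p in range(a.start, a.end + 1)
                if start <= p <= end
            ]
            gk_pos = [
                p for a in assigned for p in a.gatekeeper_positions
                if start <= p <= end
            ]
            infos.append(_DomainInfo(dom, intent, strongest, apr_pos, gk_pos))
        if not ok:
            continue

        # disorder track: low baseline, optional high segment
        dis = rng.uniform(0.05, 0.35, size=L)
        if rng.random() < cfg.disorder_segment_prob:
            slen = int(rng.integers(cfg.disorder_segment_length_range[0],
                                    cfg.disorder_segment_length_range[1] + 1))
            slen = min(slen, L)
            s0 = int(rng.integers(0, L - slen + 1))
            dis[s0 : s0 + slen] = rng.uniform(0.6, 0.95, size=slen)
        return protein, track, DisorderTrack(pid, dis), infos, aprs
    raise ValidationError(
        f"could not generate a protein matching the planted intent for {pid}"
    )


def _truncated_normal_geq(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    raise ValidationError("truncated ddG sampler failed; check mixture params")


def _mixture_draw(
    rng: np.random.Generator,
    mixture: tuple[tuple[float, float, float], ...],
) -> float:
    weights = np.array([c[0] for c in mixture])
    i = rng.choice(len(mixture), p=weights / weights.sum())
    return float(rng.normal(mixture[i][1], mixture[i][2]))


def _category_positions(info: _DomainInfo, category: str) -> list[int]:
    """Candidate positions for a site category within one domain."""
    return {
        "in_apr": info.apr_positions,
        "gatekeeper": info.gatekeeper_positions,
        "disorder": info.disorder_positions,
        "other": info.other_positions,
    }[category]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    # resample the proteome in the (rare) event that it contains no strong
    # or no non-strong domain at all, so every cohort can be placed
    for _proteome_try in range(20):
        proteins, domains, infos = [], [], []
        tracks: dict[str, ScoreTrack] = {}
        disorder: dict[str, DisorderTrack] = {}
        for i in range(config.n_proteins):
            pid = f"synp{i + 1:04d}"
            protein, track, dis, dinfos, _ = _generate_protein(config, rng, pid)
            proteins.append(protein)
            tracks[pid] = track
            disorder[pid] = dis
            for info in dinfos:
                domains.append(info.annotation)
                infos.append(info)
        if any(d.strongest > STRONG_APR_SCORE for d in infos) and any(
            d.strongest <= STRONG_APR_SCORE for d in infos
        ):
            break
    else:
        raise ValidationError(
            "proteome lacks strong or non-strong domains; increase n_proteins "
            "or adjust APR planting probabilities"
        )

    for info in infos:
        d = info.annotation
        dis = disorder[d.protein_id].scores
        apr_set = set(info.apr_positions)
        gk_set = set(info.gatekeeper_positions)
        info.disorder_positions = [
            p for p in range(d.start, d.end + 1)
            if dis[p - 1] >= 0.5 and p not in apr_set
        ]
        info.other_positions = [
            p for p in range(d.start, d.end + 1)
            if p not in apr_set and p not in gk_set
        ] or list(range(d.start, d.end + 1))

    strong = [d for d in infos if d.strongest > STRONG_APR_SCORE]
    weak = [d for d in infos if d.strongest <= STRONG_APR_SCORE]
    protein_map = {p.protein_id: p for p in proteins}
    # planted variants live in strong domains; non-planted variants prefer
    # non-strong domains but may fall back to a strong domain (their ddG is
    # then truncated below the strong cut so the combined rule stays False)
    eligible_cache: dict[tuple[bool, str], list[_DomainInfo]] = {}
    for category in ("in_apr", "gatekeeper", "disorder", "other"):
        strong_cand = [d for d in strong if _category_positions(d, category)]
        weak_cand = [d for d in weak if _category_positions(d, category)]
        eligible_cache[(True, category)] = strong_cand or strong
        eligible_cache[(False, category)] = weak_cand or strong_cand or weak

    variants: list[Variant] = []
    ddgs: list[StabilityRecord] = []
    truth: list[GroundTruth] = []
    seen: set[tuple[str, int, str, str]] = set()

    for label, spec in (("pathogenic", config.pathogenic),
                        ("neutral", config.neutral)):
        for _ in range(spec.n):
            # the planted flag is drawn once per variant so that position
            # collisions during placement cannot bias the prevalence
            planted = bool(rng.random() < spec.prevalence)
            key = None
            for _attempt in range(1000):
                u = rng.random()
                if u < spec.p_apr_site:
                    category = "in_apr"
                elif u < spec.p_apr_site + spec.p_gatekeeper_site:
                    category = "gatekeeper"
                elif u < (spec.p_apr_site + spec.p_gatekeeper_site
                          + spec.p_disorder_site):
                    category = "disorder"
                else:
                    category = "other"
                eligible = eligible_cache[(planted, category)]
                info = eligible[rng.integers(len(eligible))]
                pid = info.annotation.protein_id
                cand = _category_positions(info, category) or _category_positions(
                    info, "other"
                )
                pos = int(rng.choice(cand))
                wt = protein_map[pid].residue(pos)
                # try every mutant residue at this position before rejecting it
                for mut in rng.permutation(_ALL_AAS[_ALL_AAS != wt]):
                    if (pid, pos, wt, str(mut)) not in seen:
                        key = (pid, pos, wt, str(mut))
                        break
                if key is not None:
                    seen.add(key)
                    mut = key[3]
                    break
            else:
                raise ValidationError("could not draw a fresh variant")

            if planted:
                ddg = _truncated_normal_geq(
                    rng, config.planted_ddg_mean, config.planted_ddg_sd,
                    DDG_STRONG,
                )
            else:
                in_strong = info.strongest > STRONG_APR_SCORE
                for _ in range(10000):
                    ddg = _mixture_draw(rng, spec.ddg_mixture)
                    if config.ddg_apr_correlation:
                        ddg += config.ddg_apr_correlation * (
                            info.strongest / STRONG_APR_SCORE
                        )
                    if not (in_strong and ddg >= DDG_STRONG):
                        break
                else:
                    raise ValidationError(
                        "could not draw a sub-threshold ddG; check mixture"
                    )

            v = Variant(pid, pos, wt, mut, label)
            variants.append(v)
            ddgs.append(StabilityRecord(pid, pos, wt, mut, float(ddg)))
            # ground truth from realized data, and cross-checked
            realized_agg = (
                ddg >= DDG_STRONG and info.strongest > STRONG_APR_SCORE
            )
            assert realized_agg == planted
            truth.append(
                GroundTruth(
                    variant=v,
                    aggregation_increasing=realized_agg,
                    site_category=(
                        "in_apr" if pos in info.apr_positions
                        else "gatekeeper" if pos in info.gatekeeper_positions
                        else "other"
                    ),
                    disordered_site=bool(disorder[pid].scores[pos - 1] >= 0.5),
                    in_strong_domain=info.strongest > STRONG_APR_SCORE,
                )
            )

    return SyntheticDataset(
        config=config,
        proteins=proteins,
        tracks=tracks,
        disorder=disorder,
        domains=domains,
        variants=variants,
        ddgs=ddgs,
        ground_truth=truth,
    )


def null_config(config: SyntheticConfig, prevalence: float = 0.15) -> SyntheticConfig:
    """A config in which both cohorts share one generative process."""
    shared = replace(
        config.neutral,
        prevalence=prevalence,
        n=config.neutral.n,
    )
    return replace(
        config,
        pathogenic=replace(shared, n=config.pathogenic.n),
        neutral=shared,
    )


def generate_null(config: SyntheticConfig, prevalence: float = 0.15) -> SyntheticDataset:
    """Generate a dataset with NO planted cohort difference (both cohorts
    drawn from the identical process), for statistical calibration."""
    return generate(null_config(config, prevalence))
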