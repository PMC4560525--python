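import numpy as np
import pytest

from aggrevar import (
    DisorderTrack,
    Direction,
    DomainAnnotation,
    IntrinsicCategory,
    ProteinRecord,
    StabilityClass,
    StabilityRecord,
    Variant,
    call_aprs,
    call_and_annotate,
    classify_cohort,
    classify_disorder,
    classify_intrinsic,
    classify_stability,
    is_aggregation_increasing,
    mutate_and_rescore,
    score_sequence,
)
from aggrevar.aprs import GATEKEEPER_RESIDUES
from conftest import make_track


class TestStabilityClass:
    @pytest.mark.parametrize(
        "ddg, expected",
        [
            (-0.51, StabilityClass.STABILIZING),
            (-0.5, StabilityClass.NEUTRAL),
            (0.0, StabilityClass.NEUTRAL),
            (0.5, StabilityClass.NEUTRAL),
            (0.51, StabilityClass.DESTABILIZING),
            (1.99, StabilityClass.DESTABILIZING),
            (2.0, StabilityClass.STRONGLY_DESTABILIZING),
            (7.3, StabilityClass.STRONGLY_DESTABILIZING),
        ],
    )
    def test_thresholds(self, ddg, expected):
        assert classify_stability(ddg) is expected


class TestCombinedRule:
    @pytest.mark.parametrize(
        "ddg, score, expected",
        [
            (1.99, 70.0, False),
            (1.99, 70.1, False),
            (2.0, 70.0, False),   # strict > on the APR score
            (2.0, 70.1, True),    # inclusive >= on ddG
            (1.99, 500.0, False),
            (5.0, 70.0, False),
        ],
    )
    def test_boundary_forms(self, ddg, score, expected):
        assert is_aggregation_increasing(ddg, score) is expected

    def test_missing_inputs_give_na(self):
        assert is_aggregation_increasing(None, 100.0) is None
        assert is_aggregation_increasing(3.0, None) is None

    def test_raising_ddg_never_unsets_the_flag(self, rng):
        for _ in range(50):
            score = rng.uniform(0, 300)
            ddgs = np.sort(rng.uniform(-3, 8, size=6))
            flags = [is_aggregation_increasing(d, score) for d in ddgs]
            assert flags == sorted(flags)  # False before True, never back


class TestDisorder:
    track = DisorderTrack("p1", [0.9, 0.1, 0.5])

    @pytest.mark.parametrize("pos, expected", [(1, True), (2, False), (3, True)])
    def test_cutoff_inclusive(self, pos, expected):
        v = Variant("p1", pos, "A", "V")
        assert classify_disorder(v, self.track) is expected

    def test_missing_track_is_na(self):
        assert classify_disorder(Variant("p1", 1, "A", "V"), None) is None


def annotated(track, seq):
    return call_and_annotate(track, ProteinRecord("p1", seq))


class TestClassifyIntrinsic:
    def test_in_apr_increase(self):
        seq = "A" * 12
        wt = make_track("p1", [0, 0, 6, 6, 6, 6, 6, 0, 0, 0, 0, 0])
        mut = make_track("p1", [0, 0, 7, 7, 7, 7, 7, 0, 0, 0, 0, 0])
        eff = classify_intrinsic(
            annotated(wt, seq), call_aprs(mut), wt, mut, Variant("p1", 5, "A", "V")
        )
        assert eff.category is IntrinsicCategory.IN_APR
        assert eff.direction is Direction.INCREASE
        assert eff.delta_score == pytest.approx(5.0)

    def test_gatekeeper_neutral_when_delta_within_tolerance(self):
        seq = "AA" + "IIIII" + "K" + "AAAA"
        wt = make_track("p1", [0, 0, 6, 6, 6, 6, 6, 0, 0, 0, 0, 0])
        eff = classify_intrinsic(
            annotated(wt, seq), call_aprs(wt), wt, wt, Variant("p1", 8, "K", "I")
        )
        assert eff.category is IntrinsicCategory.GATEKEEPER
        assert eff.direction is Direction.NEUTRAL

    def test_flank_position_without_gatekeeper_residue_is_outside(self):
        seq = "AA" + "IIIII" + "A" + "AAAA"
        wt = make_track("p1", [0, 0, 6, 6, 6, 6, 6, 0, 0, 0, 0, 0])
        eff = classify_intrinsic(
            annotated(wt, seq), call_aprs(wt), wt, wt, Variant("p1", 8, "A", "V")
        )
        assert eff.category is IntrinsicCategory.OUTSIDE

    def test_de_novo_creation(self):
        seq = "A" * 16
        wt = make_track("p1", [0.0] * 16)
        mut = make_track("p1", [0.0] * 10 + [8.0] * 5 + [0.0])
        eff = classify_intrinsic(
            annotated(wt, seq), call_aprs(mut), wt, mut, Variant("p1", 13, "A", "I")
        )
        assert eff.category is IntrinsicCategory.DE_NOVO_APR
        assert eff.direction is Direction.INCREASE

    def test_de_novo_takes_precedence_over_in_apr(self):
        seq = "A" * 24
        wt = make_track("p1", [6.0] * 5 + [0.0] * 19)
        mut = make_track("p1", [6.0] * 5 + [0.0] * 5 + [8.0] * 5 + [0.0] * 9)
        eff = classify_intrinsic(
            annotated(wt, seq), call_aprs(mut), wt, mut, Variant("p1", 3, "A", "V")
        )
        assert eff.category is IntrinsicCategory.DE_NOVO_APR

    def test_track_length_mismatch_rejected(self):
        wt = make_track("p1", [0.0] * 10)
        mut = make_track("p1", [0.0] * 11)
        with pytest.raises(Exception, match="length"):
            classify_intrinsic([], [], wt, mut, Variant("p1", 1, "A", "V"))


def brute_force_intrinsic(protein, variant):
    """Independent re-derivation of the intrinsic category from raw scores."""
    wt_track = score_sequence(protein)
    _, mut_track = mutate_and_rescore(protein, variant)

    def runs(scores):
        out, cur = [], []
        for i, s in enumerate(scores, 1):
            if s > 5.0:
                cur.append(i)
            else:
                if len(cur) >= 5:
                    out.append((cur[0], cur[-1]))
                cur = []
        if len(cur) >= 5:
            out.append((cur[0], cur[-1]))
        return out

    wt_runs = runs(wt_track.scores)
    mut_runs = runs(mut_track.scores)
    for ms, me in mut_runs:
        if all(me < ws or we < ms for ws, we in wt_runs):
            return "DE_NOVO_APR"
    if any(ws <= variant.position <= we for ws, we in wt_runs):
        return "IN_APR"
    for ws, we in wt_runs:
        flanks = [p for p in range(ws - 3, ws) if p >= 1] + [
            p for p in range(we + 1, we + 4) if p <= protein.length
        ]
        if variant.position in flanks and variant.wt_aa in GATEKEEPER_RESIDUES:
            return "GATEKEEPER"
    return "OUTSIDE"


class TestExhaustiveScanOracle:
    def test_all_substitutions_of_fixture_match_brute_force(self):
        """Every possible substitution of a 30-residue fixture classifies
        identically via the pipeline and an independent re-derivation."""
        protein = ProteinRecord(
            "fx", "MKTEIVLIVAGKDNSPRLIVLFAEESTGHW"
        )
        wt_track = score_sequence(protein)
        wt_aprs = call_and_annotate(wt_track, protein)
        mismatches = []
        for pos in range(1, protein.length + 1):
            wt_aa = protein.residue(pos)
            for mut_aa in "ACDEFGHIKLMNPQRSTVWY":
                if mut_aa == wt_aa:
                    continue
                v = Variant("fx", pos, wt_aa, mut_aa)
                _, mut_track = mutate_and_rescore(protein, v)
                eff = classify_intrinsic(
                    wt_aprs, call_aprs(mut_track), wt_track, mut_track, v
                )
                expected = brute_force_intrinsic(protein, v)
                if eff.category.value != expected:
                    mismatches.append((pos, mut_aa, eff.category.value, expected))
        assert mismatches == []


class TestClassifyCohort:
    @pytest.fixture
    def setup(self):
        protein = ProteinRecord("p1", "SGSNGS" + "IVLVIVL" + "KGSNGSAAAA")
        domains = [DomainAnnotation("p1", "d1", 3, 18)]
        return protein, domains

    def test_empty_variant_list(self, setup):
        protein, domains = setup
        cls, summary = classify_cohort({"p1": protein}, [], domains=domains)
        assert cls == []
        assert summary["n_variants"] == 0

    def test_variant_without_ddg_is_na_not_dropped(self, setup):
        protein, domains = setup
        v = Variant("p1", 8, "V", "A", "pathogenic")
        cls, summary = classify_cohort({"p1": protein}, [v], domains=domains)
        (c,) = cls
        assert c.ddg is None
        assert c.aggregation_increasing is None
        assert summary["cohorts"]["pathogenic"]["n_excluded_no_ddg"] == 1

    def test_combined_rule_uses_wild_type_domain_signature(self, setup):
        protein, domains = setup
        v = Variant("p1", 8, "V", "A", "pathogenic")
        ddg = [StabilityRecord("p1", 8, "V", "A", 3.2)]
        cls, _ = classify_cohort({"p1": protein}, [v], ddgs=ddg, domains=domains)
        (c,) = cls
        wt_aprs = call_and_annotate(score_sequence(protein), protein)
        assert c.domain_strongest_apr == pytest.approx(
            max(a.region_score for a in wt_aprs)
        )
        assert c.aggregation_increasing is (c.domain_strongest_apr > 70.0)

    def test_linker_variant_excluded_from_rule_denominator(self, setup):
        protein, domains = setup
        v = Variant("p1", 20, "A", "V", "neutral")
        ddg = [StabilityRecord("p1", 20, "A", "V", 4.0)]
        cls, summary = classify_cohort({"p1": protein}, [v], ddgs=ddg, domains=domains)
        assert cls[0].domain_id is None
        assert cls[0].aggregation_increasing is None
        assert summary["cohorts"]["neutral"]["n_excluded_no_domain"] == 1

    def test_summary_fractions_match_table_recount(self):
        import aggrevar as av

        ds = av.generate(
            av.SyntheticConfig(
                seed=7,
                n_proteins=15,
                pathogenic=av.CohortSpec(
                    n=300, prevalence=0.225, p_apr_site=0.154,
                    p_gatekeeper_site=0.12, p_disorder_site=0.12,
                    ddg_mixture=((0.6, 3.0, 1.5), (0.4, 0.5, 1.0)),
                ),
                neutral=av.CohortSpec(
                    n=150, prevalence=0.075, p_apr_site=0.113,
                    p_gatekeeper_site=0.08, p_disorder_site=0.24,
                    ddg_mixture=((1.0, 0.3, 1.0),),
                ),
            )
        )
        cls, summary = classify_cohort(
            ds.protein_map, ds.variants, ddgs=ds.ddgs, domains=ds.domains,
            tracks=ds.tracks, disorder=ds.disorder,
        )
        for label in ("pathogenic", "neutral"):
            sub = [c for c in cls if c.variant.label == label]
            got = summary["cohorts"][label]
            assert got["n"] == len(sub)
            recount = sum(
                1 for c in sub if c.intrinsic.category is IntrinsicCategory.IN_APR
            ) / len(sub)
            assert got["frac_in_apr"] == pytest.approx(recount)
            denom = [c for c in sub if c.aggregation_increasing is not None]
            assert got["frac_aggregation_increasing"] == pytest.approx(
                sum(bool(c.aggregation_increasing) for c in denom) / len(denom)
            )

    def test_every_variant_gets_exactly_one_category(self, setup):
        protein, domains = setup
        variants = [
            Variant("p1", p, protein.residue(p), "W" if protein.residue(p) != "W" else "F")
            for p in range(1, protein.length + 1)
        ]
        cls, _ = classify_cohort({"p1": protein}, variants, domains=domains)
        assert len(cls) == len(variants)
        assert all(isinstance(c.intrinsic.category, IntrinsicCategory) for c in cls)
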