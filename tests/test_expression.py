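"""Presence matrices, ordinal grading and the four-way comparison grid."""

from __future__ import annotations

from itertools import chain, combinations

import pytest

from wntdiverge.errors import (
    IncompleteSubfamilyError,
    StageError,
    UndefinedIndexError,
    VocabularyError,
)
from wntdiverge.expression import (
    Aggregation,
    ComparisonKind,
    ComparisonResult,
    ExpressionAnnotation,
    GeneId,
    ParalogueTag,
    SimilarityGrade,
    StageMap,
    Territory,
    build_presence_matrix,
    compare_subfamily,
    divergence_index,
    grade_from_sets,
    grade_pair,
)
from wntdiverge.vocab import CHICK, DEFAULT_STAGE_MAP, MOUSE


def gene(subfamily: str, tag: str, species: str) -> GeneId:
    return GeneId(subfamily, ParalogueTag(tag), species)


def ann(g: GeneId, stage: str, territory: str, *domains: str) -> ExpressionAnnotation:
    return ExpressionAnnotation(g, stage, territory, frozenset(domains))


def powerset(universe):
    return [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(universe, k) for k in range(len(universe) + 1)
        )
    ]


# ---------------------------------------------------------------------------
# grading axioms


@pytest.mark.parametrize(
    "d1, d2, expected",
    [
        (frozenset(), frozenset(), SimilarityGrade.NOT_APPLICABLE),
        (frozenset({"dorsal_ectoderm"}), frozenset(), SimilarityGrade.EXCLUSIVE),
        (
            frozenset({"dorsal_ectoderm"}),
            frozenset({"proximoventral_ectoderm"}),
            SimilarityGrade.DIFF_DOMAIN,
        ),
        (
            frozenset({"dorsal_ectoderm", "AER"}),
            frozenset({"dorsal_ectoderm"}),
            SimilarityGrade.MINOR_DIFF,
        ),
        (
            frozenset({"dorsal_ectoderm"}),
            frozenset({"dorsal_ectoderm"}),
            SimilarityGrade.EQUAL,
        ),
    ],
)
def test_grade_from_sets_cases(d1, d2, expected):
    assert grade_from_sets(d1, d2) is expected
    assert grade_from_sets(d2, d1) is expected  # symmetry


def test_grade_axioms_exhaustive():
    """Over every pair of subsets of a 4-domain universe: symmetry, EQUAL
    iff identical sets, EXCLUSIVE iff exactly one empty, NOT_APPLICABLE iff
    both empty."""
    universe = ["d1", "d2", "d3", "d4"]
    for a in powerset(universe):
        for b in powerset(universe):
            g = grade_from_sets(a, b)
            assert g is grade_from_sets(b, a)
            assert (g is SimilarityGrade.EQUAL) == (a == b and bool(a))
            assert (g is SimilarityGrade.EXCLUSIVE) == (bool(a) != bool(b))
            assert (g is SimilarityGrade.NOT_APPLICABLE) == (not a and not b)
            if g is SimilarityGrade.MINOR_DIFF:
                assert a & b and a != b
            if g is SimilarityGrade.DIFF_DOMAIN:
                assert a and b and not (a & b)


def test_grade_pair_exhaustive_via_annotations():
    """grade_pair with stage-union aggregation reduces to the set rule for
    single-territory annotations; checked over all 2^4 x 2^4 domain-set
    pairs, in both argument orders."""
    universe = ["d1", "d2", "d3", "d4"]
    territory = Territory("t", "t", None)
    g1 = gene("Wnt5", "A", MOUSE)
    g2 = gene("Wnt5", "B", MOUSE)
    for a in powerset(universe):
        for b in powerset(universe):
            annotations = []
            if a:
                annotations.append(ExpressionAnnotation(g1, "TS15", "t", a))
            if b:
                annotations.append(ExpressionAnnotation(g2, "TS17", "t", b))
            got = grade_pair(g1, g2, territory, annotations)
            rev = grade_pair(g2, g1, territory, annotations)
            assert got is grade_from_sets(a, b)
            assert rev is got


def test_grade_pair_cross_species_requires_stage_map():
    territory = Territory("t", "t", None)
    g1 = gene("Wnt5", "A", MOUSE)
    g2 = gene("Wnt5", "A", CHICK)
    with pytest.raises(StageError):
        grade_pair(g1, g2, territory, [])


def test_grade_pair_stage_aggregations():
    """A pair equal at matched early stages but divergent later: the union
    view and the worst per-stage view see a difference, the best per-stage
    view still sees equality."""
    territory = Territory("t", "t", None)
    g1 = gene("Wnt5", "A", MOUSE)
    g2 = gene("Wnt5", "A", CHICK)
    annotations = [
        ann(g1, "TS15", "t", "dorsal"),
        ann(g2, "HH20", "t", "dorsal"),
        ann(g1, "TS19", "t", "ventral"),
        ann(g2, "HH26", "t", "roof"),
    ]
    sm = DEFAULT_STAGE_MAP
    assert (
        grade_pair(g1, g2, territory, annotations, sm, Aggregation.UNION_OVER_STAGES)
        is SimilarityGrade.MINOR_DIFF
    )
    assert (
        grade_pair(g1, g2, territory, annotations, sm, Aggregation.PER_STAGE_WORST)
        is SimilarityGrade.DIFF_DOMAIN
    )
    assert (
        grade_pair(g1, g2, territory, annotations, sm, Aggregation.PER_STAGE_BEST)
        is SimilarityGrade.EQUAL
    )


def test_identical_per_stage_sets_equal_under_all_aggregations():
    territory = Territory("t", "t", None)
    g1 = gene("Wnt7", "A", MOUSE)
    g2 = gene("Wnt7", "B", MOUSE)
    annotations = []
    for stage in ("TS15", "TS17", "TS19"):
        annotations.append(ann(g1, stage, "t", "dorsal", "distal"))
        annotations.append(ann(g2, stage, "t", "dorsal", "distal"))
    for aggregation in Aggregation:
        assert (
            grade_pair(
                g1, g2, territory, annotations, DEFAULT_STAGE_MAP, aggregation
            )
            is SimilarityGrade.EQUAL
        )


# ---------------------------------------------------------------------------
# presence matrix


def test_presence_matrix_single_stage_detection():
    """Expression at a single stage is enough to mark a territory."""
    territories = [Territory("tail_bud", "tail bud", None), Territory("eye", "eye", None)]
    g = gene("Wnt8", "A", CHICK)
    matrix = build_presence_matrix(
        [ann(g, "HH20", "tail_bud", "mesoderm")], territories
    )
    assert matrix.loc[g.key].tolist() == [1, 0]


def test_presence_matrix_enumeration():
    territories = [Territory("t1", "t1", None), Territory("t2", "t2", None)]
    g1 = gene("Wnt2", "A", MOUSE)
    g2 = gene("Wnt2", "B", MOUSE)
    g3 = gene("Wnt2", "A", CHICK)
    annotations = [
        ann(g1, "TS15", "t1", "d"),
        ann(g2, "TS15", "t1", "d"),
        ann(g2, "TS17", "t2", "d"),
    ]
    matrix = build_presence_matrix(annotations, territories, genes=[g1, g2, g3])
    assert matrix.values.tolist() == [[1, 0], [1, 1], [0, 0]]


def test_presence_matrix_empty_and_unknown():
    territories = [Territory("t1", "t1", None)]
    assert build_presence_matrix([], territories).values.size == 0
    with pytest.raises(VocabularyError):
        build_presence_matrix(
            [ann(gene("Wnt2", "A", MOUSE), "TS15", "nowhere", "d")], territories
        )


def test_presence_zero_implies_exclusive_or_na():
    """If a gene is absent from a territory, every grade involving it there
    is EXCLUSIVE or NOT_APPLICABLE."""
    territories = [Territory("t1", "t1", None), Territory("t2", "t2", None)]
    g1 = gene("Wnt2", "A", MOUSE)
    g2 = gene("Wnt2", "B", MOUSE)
    annotations = [ann(g2, "TS15", "t1", "d")]
    matrix = build_presence_matrix(annotations, territories, genes=[g1, g2])
    for t in territories:
        assert matrix.loc[g1.key, t.id] == 0
        g = grade_pair(g1, g2, t, annotations)
        assert g in (SimilarityGrade.EXCLUSIVE, SimilarityGrade.NOT_APPLICABLE)


# ---------------------------------------------------------------------------
# subfamily grid


def test_compare_subfamily_limb_toy(limb_annotations, limb_territories):
    """Conserved complementary deployment: a-orthologues EQUAL (dorsal
    ectoderm in both species), paralogues DIFF_DOMAIN in both species."""
    result = compare_subfamily(
        "Wnt7", limb_annotations, limb_territories, DEFAULT_STAGE_MAP
    )
    cell = result.grid
    assert cell[("limb_ectoderm", ComparisonKind.ORTHOLOGUES_A)] is SimilarityGrade.EQUAL
    assert cell[("limb_ectoderm", ComparisonKind.ORTHOLOGUES_B)] is SimilarityGrade.EQUAL
    assert (
        cell[("limb_ectoderm", ComparisonKind.PARALOGUES_SPECIES1)]
        is SimilarityGrade.DIFF_DOMAIN
    )
    assert (
        cell[("limb_ectoderm", ComparisonKind.PARALOGUES_SPECIES2)]
        is SimilarityGrade.DIFF_DOMAIN
    )
    assert result.divergence_index[ComparisonKind.ORTHOLOGUES_A] == 0.0
    assert result.divergence_index[ComparisonKind.PARALOGUES_SPECIES2] == 2.0


def test_compare_subfamily_empty_and_incomplete(limb_territories):
    registry = [
        gene("Wnt9", t, sp) for t in "AB" for sp in (MOUSE, CHICK)
    ]
    result = compare_subfamily(
        "Wnt9", [], limb_territories, DEFAULT_STAGE_MAP, genes=registry
    )
    assert result.grid == {}
    assert all(v is None for v in result.divergence_index.values())
    with pytest.raises(IncompleteSubfamilyError):
        compare_subfamily("Wnt9", [], limb_territories, DEFAULT_STAGE_MAP, genes=registry[:2])


def test_compare_subfamily_rejects_bad_stage(limb_territories):
    g = gene("Wnt7", "A", MOUSE)
    registry = [gene("Wnt7", t, sp) for t in "AB" for sp in (MOUSE, CHICK)]
    with pytest.raises(StageError):
        compare_subfamily(
            "Wnt7",
            [ann(g, "TS99", "limb_ectoderm", "d")],
            limb_territories,
            DEFAULT_STAGE_MAP,
            genes=registry,
        )


def test_divergence_index_arithmetic():
    grid = {
        ("t1", ComparisonKind.ORTHOLOGUES_A): SimilarityGrade.EQUAL,
        ("t2", ComparisonKind.ORTHOLOGUES_A): SimilarityGrade.DIFF_DOMAIN,
        ("t3", ComparisonKind.ORTHOLOGUES_A): SimilarityGrade.EXCLUSIVE,
        ("t4", ComparisonKind.ORTHOLOGUES_A): SimilarityGrade.NOT_APPLICABLE,
    }
    result = ComparisonResult("x", MOUSE, CHICK, ["t1", "t2", "t3", "t4"], grid)
    assert divergence_index(result, ComparisonKind.ORTHOLOGUES_A) == pytest.approx(5 / 3)
    with pytest.raises(UndefinedIndexError):
        divergence_index(result, ComparisonKind.ORTHOLOGUES_B)


def test_stage_map_contract():
    sm = StageMap(MOUSE, CHICK, (("TS15", "HH20"),))
    assert sm.counterpart(MOUSE, "TS15") == "HH20"
    assert sm.counterpart(CHICK, "HH20") == "TS15"
    with pytest.raises(StageError):
        sm.counterpart(MOUSE, "TS17")
    with pytest.raises(Exception):
        StageMap(MOUSE, CHICK, (("TS15", "HH20"), ("TS15", "HH23")))


def test_annotation_requires_domains():
    with pytest.raises(ValueError):
        ExpressionAnnotation(
            gene("Wnt2", "A", MOUSE), "TS15", "t1", frozenset()
        )
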