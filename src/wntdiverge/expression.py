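"""Stage- and territory-resolved expression annotations and ordinal
similarity grading.

An annotation records that a gene is expressed, at one developmental stage,
in one anatomical *territory* (mesencephalon, branchial arch 1, limb
ectoderm, ...), localized to one or more *domains* within that territory
(dorsal ectoderm, AER, ...).  Two genes' patterns in a territory are graded
on a four-step ordinal scale:

====  =============  ==================================================
=     EQUAL (0)      expressed in largely equivalent domains
*     MINOR_DIFF(1)  same territory, overlapping but unequal domain sets
**    DIFF_DOMAIN(2) same territory, disjoint domain sets
***   EXCLUSIVE (3)  only one of the two genes expressed in the territory
====  =============  ==================================================

plus NOT_APPLICABLE when neither gene is expressed there.  Averaging the
ordinal values over a comparison's applicable territories yields a
divergence index in [0, 3]: 0 for identical deployment, 3 for fully
mutually exclusive deployment.

Paralogue comparisons (a vs b within a species) set the within-genome
divergence accumulated since the gene duplication; orthologue comparisons
(same gene across the two species) set the between-lineage divergence.
Grading is purely spatial: qualitative staining strength is stored but
never consulted.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    ConfigError,
    IncompleteSubfamilyError,
    StageError,
    UndefinedIndexError,
    VocabularyError,
)


class ParalogueTag(str, enum.Enum):
    A = "A"
    B = "B"


@dataclass(frozen=True)
class GeneId:
    """One gene: a subfamily member (paralogue a or b) in one species."""

    subfamily: str
    paralogue_tag: ParalogueTag
    species: str

    @property
    def key(self) -> str:
        """Stable row key, e.g. ``mouse:Wnt2:A``."""
        return f"{self.species}:{self.subfamily}:{self.paralogue_tag.value}"


@dataclass(frozen=True)
class Territory:
    """A named anatomical region; ``parent_id`` expresses grouping (e.g.
    mesencephalon within the CNS)."""

    id: str
    name: str
    parent_id: str | None = None


class Level(str, enum.Enum):
    STRONG = "strong"
    MODERATE = "moderate"
    WEAK = "weak"


@dataclass(frozen=True)
class ExpressionAnnotation:
    """Gene g expressed at one stage in one territory, in >=1 domains."""

    gene: GeneId
    stage: str
    territory_id: str
    domains: frozenset[str]
    level: Level | None = None

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(
                "an annotation must name at least one expression domain "
                f"({self.gene.key} @ {self.territory_id}, {self.stage})"
            )


@dataclass(frozen=True)
class StageMap:
    """Bijective correspondence between the two species' stage series."""

    species1: str
    species2: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        s1 = [a for a, _ in self.pairs]
        s2 = [b for _, b in self.pairs]
        if len(set(s1)) != len(s1) or len(set(s2)) != len(s2):
            raise ConfigError("stage map is not bijective")

    def stages_for(self, species: str) -> tuple[str, ...]:
        if species == self.species1:
            return tuple(a for a, _ in self.pairs)
        if species == self.species2:
            return tuple(b for _, b in self.pairs)
        raise StageError(f"species {species!r} not covered by the stage map")

    def counterpart(self, species: str, stage: str) -> str:
        """The matched stage in the other species."""
        for a, b in self.pairs:
            if species == self.species1 and stage == a:
                return b
            if species == self.species2 and stage == b:
                return a
        raise StageError(f"stage {stage!r} of {species!r} has no counterpart")


class SimilarityGrade(enum.Enum):
    """Ordinal spatial-similarity grade; lower is more similar."""

    EQUAL = 0
    MINOR_DIFF = 1
    DIFF_DOMAIN = 2
    EXCLUSIVE = 3
    NOT_APPLICABLE = None

    @property
    def ordinal(self) -> int | None:
        return self.value

    @property
    def symbol(self) -> str:
        return _GRADE_SYMBOLS[self]


_GRADE_SYMBOLS = {
    SimilarityGrade.EQUAL: "=",
    SimilarityGrade.MINOR_DIFF: "*",
    SimilarityGrade.DIFF_DOMAIN: "**",
    SimilarityGrade.EXCLUSIVE: "***",
    SimilarityGrade.NOT_APPLICABLE: ".",
}

SYMBOL_TO_GRADE = {s: g for g, s in _GRADE_SYMBOLS.items()}


def grade_from_sets(d1: frozenset[str], d2: frozenset[str]) -> SimilarityGrade:
    """Grade two (aggregated) domain sets within one territory.

    The rule is symmetric and depends only on emptiness, equality and
    overlap of the two sets.
    """
    if not d1 and not d2:
        return SimilarityGrade.NOT_APPLICABLE
    if not d1 or not d2:
        return SimilarityGrade.EXCLUSIVE
    if d1 == d2:
        return SimilarityGrade.EQUAL
    if d1 & d2:
        return SimilarityGrade.MINOR_DIFF
    return SimilarityGrade.DIFF_DOMAIN


class Aggregation(str, enum.Enum):
    """How per-stage domain sets are combined before grading.

    UNION_OVER_STAGES grades the union of each gene's domains across its
    stages (the summary view).  The per-stage modes grade each matched
    stage pair separately and keep the worst (most divergent) or best
    (most similar) applicable grade.
    """

    UNION_OVER_STAGES = "union"
    PER_STAGE_WORST = "worst"
    PER_STAGE_BEST = "best"


# ---------------------------------------------------------------------------
# presence matrix


def build_presence_matrix(
    annotations: Sequence[ExpressionAnnotation],
    territories: Sequence[Territory],
    genes: Sequence[GeneId] | None = None,
) -> pd.DataFrame:
    """Binary gene x territory matrix: 1 iff the gene is expressed in the
    territory at *any* stage.

    Rows follow ``genes`` if given, else first-appearance order in
    ``annotations``; columns follow the territory vocabulary order.
    """
    known = {t.id for t in territories}
    if genes is None:
        ordered: list[GeneId] = []
        seen: set[str] = set()
        for ann in annotations:
            if ann.gene.key not in seen:
                seen.add(ann.gene.key)
                ordered.append(ann.gene)
        genes = ordered
    matrix = pd.DataFrame(
        0,
        index=pd.Index([g.key for g in genes], name="gene"),
        columns=pd.Index([t.id for t in territories], name="territory"),
        dtype=int,
    )
    for ann in annotations:
        if ann.territory_id not in known:
            raise VocabularyError(
                f"unknown territory id {ann.territory_id!r} "
                f"(gene {ann.gene.key}, stage {ann.stage})"
            )
        if ann.gene.key in matrix.index:
            matrix.loc[ann.gene.key, ann.territory_id] = 1
    return matrix


# ---------------------------------------------------------------------------
# grading


def _domains_at(
    annotations: Iterable[ExpressionAnnotation],
    gene: GeneId,
    territory_id: str,
    stage: str | None,
) -> frozenset[str]:
    """Domain set of ``gene`` in ``territory_id``; one stage or the union."""
    out: set[str] = set()
    for ann in annotations:
        if ann.gene == gene and ann.territory_id == territory_id:
            if stage is None or ann.stage == stage:
                out |= ann.domains
    return frozenset(out)


def grade_pair(
    g1: GeneId,
    g2: GeneId,
    territory: Territory,
    annotations: Sequence[ExpressionAnnotation],
    stage_map: StageMap | None = None,
    aggregation: Aggregation = Aggregation.UNION_OVER_STAGES,
) -> SimilarityGrade:
    """Grade the spatial similarity of two genes' patterns in a territory.

    Cross-species comparisons require a stage map so that per-stage modes
    compare morphologically matched stages (TS15 with HH20, etc.).
    """
    cross_species = g1.species != g2.species
    if cross_species and stage_map is None:
        raise StageError(
            f"comparing {g1.key} with {g2.key} across species requires a "
            "stage map"
        )

    if aggregation is Aggregation.UNION_OVER_STAGES:
        d1 = _domains_at(annotations, g1, territory.id, None)
        d2 = _domains_at(annotations, g2, territory.id, None)
        return grade_from_sets(d1, d2)

    # per-stage modes: grade each matched stage pair, combine
    assert stage_map is not None or not cross_species
    if stage_map is not None:
        stages1 = stage_map.stages_for(g1.species)
    else:
        stages1 = tuple(
            sorted({a.stage for a in annotations if a.gene.species == g1.species})
        )
    per_stage: list[SimilarityGrade] = []
    for s1 in stages1:
        s2 = stage_map.counterpart(g1.species, s1) if cross_species else s1
        d1 = _domains_at(annotations, g1, territory.id, s1)
        d2 = _domains_at(annotations, g2, territory.id, s2)
        per_stage.append(grade_from_sets(d1, d2))
    applicable = [g for g in per_stage if g is not SimilarityGrade.NOT_APPLICABLE]
    if not applicable:
        return SimilarityGrade.NOT_APPLICABLE
    if aggregation is Aggregation.PER_STAGE_WORST:
        return max(applicable, key=lambda g: g.ordinal)
    return min(applicable, key=lambda g: g.ordinal)


# ---------------------------------------------------------------------------
# subfamily comparison grid


class ComparisonKind(str, enum.Enum):
    PARALOGUES_SPECIES1 = "PARALOGUES_SPECIES1"
    PARALOGUES_SPECIES2 = "PARALOGUES_SPECIES2"
    ORTHOLOGUES_A = "ORTHOLOGUES_A"
    ORTHOLOGUES_B = "ORTHOLOGUES_B"


@dataclass
class ComparisonResult:
    """Four-way comparison grid of one subfamily, plus per-column means."""

    subfamily: str
    species1: str
    species2: str
    territory_order: list[str]
    grid: dict[tuple[str, ComparisonKind], SimilarityGrade]
    divergence_index: dict[ComparisonKind, float | None] = field(
        default_factory=dict
    )

    def column(self, kind: ComparisonKind) -> dict[str, SimilarityGrade]:
        return {
            t: g for (t, k), g in self.grid.items() if k is kind
        }

    def to_dict(self) -> dict:
        return {
            "subfamily": self.subfamily,
            "species1": self.species1,
            "species2": self.species2,
            "territory_order": list(self.territory_order),
            "grid": {
                t: {
                    k.value: self.grid[(t, k)].symbol
                    for k in ComparisonKind
                    if (t, k) in self.grid
                }
                for t in self.territory_order
            },
            "divergence_index": {
                k.value: (None if v is None else round(v, 6))
                for k, v in self.divergence_index.items()
            },
        }


def divergence_index(result: ComparisonResult, kind: ComparisonKind) -> float:
    """Mean ordinal grade over the applicable cells of one grid column."""
    ordinals = [
        g.ordinal
        for (_, k), g in result.grid.items()
        if k is kind and g is not SimilarityGrade.NOT_APPLICABLE
    ]
    if not ordinals:
        raise UndefinedIndexError(
            f"no applicable cells for {kind.value} in {result.subfamily}"
        )
    return sum(ordinals) / len(ordinals)


def _pairs_for(
    subfamily: str, species1: str, species2: str
) -> dict[ComparisonKind, tuple[GeneId, GeneId]]:
    def gene(species: str, tag: ParalogueTag) -> GeneId:
        return GeneId(subfamily, tag, species)

    return {
        ComparisonKind.PARALOGUES_SPECIES1: (
            gene(species1, ParalogueTag.A),
            gene(species1, ParalogueTag.B),
        ),
        ComparisonKind.PARALOGUES_SPECIES2: (
            gene(species2, ParalogueTag.A),
            gene(species2, ParalogueTag.B),
        ),
        ComparisonKind.ORTHOLOGUES_A: (
            gene(species1, ParalogueTag.A),
            gene(species2, ParalogueTag.A),
        ),
        ComparisonKind.ORTHOLOGUES_B: (
            gene(species1, ParalogueTag.B),
            gene(species2, ParalogueTag.B),
        ),
    }


def compare_subfamily(
    subfamily: str,
    annotations: Sequence[ExpressionAnnotation],
    territories: Sequence[Territory],
    stage_map: StageMap,
    genes: Sequence[GeneId] | None = None,
    aggregation: Aggregation = Aggregation.UNION_OVER_STAGES,
) -> ComparisonResult:
    """Build the four-way grid (paralogues within each species, orthologues
    for each tag) over every territory where any of the four genes is
    expressed.

    ``genes`` is the dataset's gene registry; if omitted it is taken from
    the annotations, which then must mention all four subfamily genes.
    """
    sp1, sp2 = stage_map.species1, stage_map.species2
    pairs = _pairs_for(subfamily, sp1, sp2)
    required = {
        GeneId(subfamily, tag, sp)
        for sp in (sp1, sp2)
        for tag in ParalogueTag
    }
    registry = (
        set(genes)
        if genes is not None
        else {a.gene for a in annotations}
    )
    missing = required - registry
    if missing:
        raise IncompleteSubfamilyError(
            f"subfamily {subfamily!r} incomplete; missing "
            f"{sorted(g.key for g in missing)}"
        )

    known = {t.id for t in territories}
    for ann in annotations:
        if ann.territory_id not in known:
            raise VocabularyError(
                f"unknown territory id {ann.territory_id!r} "
                f"(gene {ann.gene.key})"
            )
        series = stage_map.stages_for(ann.gene.species)
        if ann.stage not in series:
            raise StageError(
                f"stage {ann.stage!r} is not in the {ann.gene.species} "
                f"series {list(series)}"
            )

    expressed: set[str] = {
        a.territory_id for a in annotations if a.gene in required
    }
    territory_order = [t.id for t in territories if t.id in expressed]
    by_id = {t.id: t for t in territories}

    grid: dict[tuple[str, ComparisonKind], SimilarityGrade] = {}
    for tid in territory_order:
        for kind, (g1, g2) in pairs.items():
            grid[(tid, kind)] = grade_pair(
                g1, g2, by_id[tid], annotations, stage_map, aggregation
            )
    result = ComparisonResult(
        subfamily=subfamily,
        species1=sp1,
        species2=sp2,
        territory_order=territory_order,
        grid=grid,
    )
    for kind in ComparisonKind:
        try:
            result.divergence_index[kind] = divergence_index(result, kind)
        except UndefinedIndexError:
            result.divergence_index[kind] = None
    return result
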