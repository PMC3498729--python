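"""Synthetic data with planted ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`simulate_alignment` plants a known conservation category in every
  column of a five-sequence alignment, so the column classifier can be
  scored against perfect labels.
* :func:`simulate_expression` grows a four-gene expression dataset per
  subfamily from an "ancestral" domain set per territory, mutating each
  gene's copy with probability ``theta``; the grade implied by the final
  domain sets is recorded as planted truth, so the comparison grid can be
  scored exactly and the divergence index can be checked for monotone
  response to ``theta``.

Neither generator attempts realism (no substitution matrices, no indel
process, no anatomy): columns and domain sets are constructed to be
unambiguous instances of their planted class under identity matching.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .expression import (
    ComparisonKind,
    ExpressionAnnotation,
    GeneId,
    ParalogueTag,
    SimilarityGrade,
    StageMap,
    Territory,
    grade_from_sets,
)
from .msa import GAP, Category, ColumnClass, SeqRole, SubfamilyAlignment, VERTEBRATE_ROLES
from .vocab import (
    DEFAULT_DOMAIN_POOL,
    DEFAULT_STAGE_MAP,
    DEFAULT_SUBFAMILIES,
    DEFAULT_TERRITORIES,
)

# cysteine is reserved for the CONSERVED_CYS class so that planted labels
# stay unambiguous under the classifier's priority rules
_AA_NO_C = tuple(sorted(set("ADEFGHIKLMNPQRSTVWY")))

#: Categories the generator can plant (everything except UNCLASSIFIED,
#: which has no canonical construction).
CONSTRUCTIBLE: tuple[Category, ...] = (
    Category.CONSERVED_CYS,
    Category.FULLY_CONSERVED,
    Category.SINGLE_GENE_DIVERGENT,
    Category.PARALOGUE_A_CONSERVED,
    Category.PARALOGUE_B_CONSERVED,
    Category.VERTEBRATE_ONLY,
    Category.OUTGROUP_GAP,
)

#: A plausible default mixture: mostly conserved columns with a sprinkling
#: of every divergence class, echoing the overall look of a real subfamily
#: alignment (~350 columns, ~24 cysteines, conservation dominating).
DEFAULT_CLASS_MIX: dict[Category, float] = {
    Category.CONSERVED_CYS: 0.07,
    Category.FULLY_CONSERVED: 0.55,
    Category.SINGLE_GENE_DIVERGENT: 0.12,
    Category.PARALOGUE_A_CONSERVED: 0.06,
    Category.PARALOGUE_B_CONSERVED: 0.06,
    Category.VERTEBRATE_ONLY: 0.06,
    Category.OUTGROUP_GAP: 0.08,
}


@dataclass
class AlignmentSimConfig:
    n_columns: int = 350
    class_mix: dict[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    seed: int = 0
    subfamily_name: str = "WntSim"

    def __post_init__(self) -> None:
        if self.n_columns < 1:
            raise ConfigError("n_columns must be >= 1")
        bad = set(self.class_mix) - set(CONSTRUCTIBLE)
        if bad:
            raise ConfigError(
                f"cannot plant categories {sorted(c.value for c in bad)}"
            )
        if any(p < 0 for p in self.class_mix.values()):
            raise ConfigError("class_mix proportions must be >= 0")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_mix proportions sum to {total}, not 1")


def _plant_column(
    category: Category, rng: np.random.Generator
) -> tuple[dict[SeqRole, str], ColumnClass]:
    def aa(exclude: str | None = None) -> str:
        pool = [a for a in _AA_NO_C if a != exclude]
        return str(rng.choice(pool))

    if category is Category.CONSERVED_CYS:
        return {r: "C" for r in SeqRole}, ColumnClass(category)
    if category is Category.OUTGROUP_GAP:
        col = {r: aa() for r in VERTEBRATE_ROLES}
        col[SeqRole.OUTGROUP] = GAP
        return col, ColumnClass(category)

    x = aa()
    if category is Category.FULLY_CONSERVED:
        return {r: x for r in SeqRole}, ColumnClass(category)
    if category is Category.SINGLE_GENE_DIVERGENT:
        odd = VERTEBRATE_ROLES[int(rng.integers(len(VERTEBRATE_ROLES)))]
        col = {r: x for r in SeqRole}
        col[odd] = aa(exclude=x)
        return col, ColumnClass(category, divergent_role=odd)
    if category is Category.PARALOGUE_A_CONSERVED:
        col = {
            SeqRole.OUTGROUP: x,
            SeqRole.S1_A: x,
            SeqRole.S2_A: x,
            SeqRole.S1_B: aa(exclude=x),
            SeqRole.S2_B: aa(exclude=x),
        }
        return col, ColumnClass(category)
    if category is Category.PARALOGUE_B_CONSERVED:
        col = {
            SeqRole.OUTGROUP: x,
            SeqRole.S1_B: x,
            SeqRole.S2_B: x,
            SeqRole.S1_A: aa(exclude=x),
            SeqRole.S2_A: aa(exclude=x),
        }
        return col, ColumnClass(category)
    if category is Category.VERTEBRATE_ONLY:
        y = aa(exclude=x)
        col = {r: y for r in VERTEBRATE_ROLES}
        col[SeqRole.OUTGROUP] = x
        return col, ColumnClass(category)
    raise ConfigError(f"cannot plant category {category.value}")


def simulate_alignment(
    cfg: AlignmentSimConfig,
) -> tuple[SubfamilyAlignment, list[ColumnClass]]:
    """Draw a category per column from ``class_mix`` and construct residues
    realizing exactly that category under identity matching."""
    rng = np.random.default_rng(cfg.seed)
    cats = [c for c in CONSTRUCTIBLE if c in cfg.class_mix]
    probs = np.array([cfg.class_mix[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    drawn = rng.choice(len(cats), size=cfg.n_columns, p=probs)
    seqs: dict[SeqRole, list[str]] = {r: [] for r in SeqRole}
    planted: list[ColumnClass] = []
    for idx in drawn:
        col, label = _plant_column(cats[int(idx)], rng)
        planted.append(label)
        for role in SeqRole:
            seqs[role].append(col[role])
    labels = {
        SeqRole.OUTGROUP: "amphioxus",
        SeqRole.S1_A: "species1_a",
        SeqRole.S1_B: "species1_b",
        SeqRole.S2_A: "species2_a",
        SeqRole.S2_B: "species2_b",
    }
    aln = SubfamilyAlignment(
        subfamily_name=cfg.subfamily_name,
        rows={r: (labels[r], "".join(seqs[r])) for r in SeqRole},
    )
    return aln, planted


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimConfig:
    territory_vocab: tuple[Territory, ...] = tuple(
        t for t in DEFAULT_TERRITORIES if t.id != "cns"
    )
    subfamilies: tuple[str, ...] = DEFAULT_SUBFAMILIES
    stage_map: StageMap = DEFAULT_STAGE_MAP
    p_express: float = 0.6
    theta: float = 0.2
    n_domains_per_territory: int = 2
    domain_pool: tuple[str, ...] = DEFAULT_DOMAIN_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.territory_vocab:
            raise ConfigError("territory vocabulary must be non-empty")
        if not (0.0 <= self.p_express <= 1.0 and 0.0 <= self.theta <= 1.0):
            raise ConfigError("p_express and theta must lie in [0, 1]")
        if self.n_domains_per_territory < 1:
            raise ConfigError("n_domains_per_territory must be >= 1")
        if len(self.domain_pool) < 2 * self.n_domains_per_territory:
            raise ConfigError(
                "domain pool must allow a disjoint replacement set "
                "(need >= 2 * n_domains_per_territory labels)"
            )


#: planted truth: subfamily -> (territory_id, kind) -> grade
TruthGrid = dict[str, dict[tuple[str, ComparisonKind], SimilarityGrade]]


def _mutate(
    domains: frozenset[str],
    pool: Sequence[str],
    n_domains: int,
    rng: np.random.Generator,
) -> frozenset[str]:
    """One mutation, chosen uniformly among the three divergence moves:
    silencing (drop everything), relocation (disjoint replacement set), or
    a minor edit (add or remove one domain, never emptying the set)."""
    move = int(rng.integers(3))
    if move == 0:
        return frozenset()
    if move == 1:
        complement = [d for d in pool if d not in domains]
        pick = rng.choice(len(complement), size=min(n_domains, len(complement)), replace=False)
        return frozenset(complement[i] for i in pick)
    # minor edit: grow by one, or shrink by one if more than one remains
    can_grow = [d for d in pool if d not in domains]
    grow = len(domains) == 1 or (can_grow and rng.integers(2) == 0)
    if grow and can_grow:
        return domains | {str(rng.choice(can_grow))}
    return domains - {str(rng.choice(sorted(domains)))}


def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[list[ExpressionAnnotation], TruthGrid]:
    """Generate annotations for 4 genes per subfamily plus planted grades.

    For each (subfamily, territory): with probability ``p_express`` an
    ancestral domain set of ``n_domains_per_territory`` labels is drawn and
    inherited by all four genes; each gene then mutates independently with
    probability ``theta``.  A gene's final set is annotated identically at
    every stage of its species, so the planted grade is the same under all
    stage aggregations.  Truth records the grade implied by the final sets
    for every territory where at least one of the four genes is expressed.
    """
    rng = np.random.default_rng(cfg.seed)
    sp1, sp2 = cfg.stage_map.species1, cfg.stage_map.species2
    annotations: list[ExpressionAnnotation] = []
    truth: TruthGrid = {}

    for subfamily in cfg.subfamilies:
        genes = {
            (sp, tag): GeneId(subfamily, tag, sp)
            for sp in (sp1, sp2)
            for tag in ParalogueTag
        }
        pairs: dict[ComparisonKind, tuple[GeneId, GeneId]] = {
            ComparisonKind.PARALOGUES_SPECIES1: (
                genes[(sp1, ParalogueTag.A)], genes[(sp1, ParalogueTag.B)]
            ),
            ComparisonKind.PARALOGUES_SPECIES2: (
                genes[(sp2, ParalogueTag.A)], genes[(sp2, ParalogueTag.B)]
            ),
            ComparisonKind.ORTHOLOGUES_A: (
                genes[(sp1, ParalogueTag.A)], genes[(sp2, ParalogueTag.A)]
            ),
            ComparisonKind.ORTHOLOGUES_B: (
                genes[(sp1, ParalogueTag.B)], genes[(sp2, ParalogueTag.B)]
            ),
        }
        truth[subfamily] = {}
        for territory in cfg.territory_vocab:
            final: dict[GeneId, frozenset[str]] = {
                g: frozenset() for g in genes.values()
            }
            if rng.random() < cfg.p_express:
                pick = rng.choice(
                    len(cfg.domain_pool),
                    size=cfg.n_domains_per_territory,
                    replace=False,
                )
                ancestral = frozenset(cfg.domain_pool[i] for i in pick)
                for g in genes.values():
                    d = ancestral
                    if rng.random() < cfg.theta:
                        d = _mutate(
                            d, cfg.domain_pool, cfg.n_domains_per_territory, rng
                        )
                    final[g] = d
            if any(final.values()):
                for kind, (g1, g2) in pairs.items():
                    truth[subfamily][(territory.id, kind)] = grade_from_sets(
                        final[g1], final[g2]
                    )
                for g, d in final.items():
                    if not d:
                        continue
                    for stage in cfg.stage_map.stages_for(g.species):
                        annotations.append(
                            ExpressionAnnotation(
                                gene=g,
                                stage=stage,
                                territory_id=territory.id,
                                domains=d,
                            )
                        )
    return annotations, truth


def registry_for(cfg: ExpressionSimConfig) -> list[GeneId]:
    """The gene registry implied by a simulation config (4 genes per
    subfamily, whether or not they received annotations)."""
    sp1, sp2 = cfg.stage_map.species1, cfg.stage_map.species2
    return [
        GeneId(subfamily, tag, sp)
        for subfamily in cfg.subfamilies
        for sp in (sp1, sp2)
        for tag in ParalogueTag
    ]
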