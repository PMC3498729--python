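"""Column-wise conservation profiling of five-sequence subfamily alignments.

The unit of analysis is a subfamily alignment holding one pre-duplication
outgroup sequence (amphioxus in the Wnt study) and the two paralogues ("a"
and "b") from each of two vertebrate species (chick and mouse).  Because the
outgroup proxies the ancestral, pre-duplication state, every column can be
read as a small phylogenetic experiment: which of the four vertebrate genes
still carry the ancestral residue?

Each column is assigned exactly one category:

``CONSERVED_CYS``
    All five residues are cysteine — the hallmark ~24 conserved cysteines of
    Wnt ligands are tabulated separately from ordinary conservation.
``FULLY_CONSERVED``
    All four vertebrate residues match the outgroup residue.
``SINGLE_GENE_DIVERGENT``
    Exactly three vertebrate residues match the outgroup; the odd one out is
    recorded as the divergent gene.  High counts flag a gene drifting away
    from the rest of its subfamily (mouse Wnt8a in the study).
``PARALOGUE_A_CONSERVED`` / ``PARALOGUE_B_CONSERVED``
    Exactly the two "a" (or exactly the two "b") paralogues match the
    outgroup — paralogue-specific conservation, the signature expected if
    the duplicates partitioned the ancestral function.
``VERTEBRATE_ONLY``
    No vertebrate matches the outgroup but all four vertebrates agree with
    each other: a substitution fixed on the vertebrate stem.
``OUTGROUP_GAP``
    The outgroup is gapped, so no comparison with the ancestral state is
    possible; such columns are excluded from every conservation count.
``UNCLASSIFIED``
    Anything else (e.g. both genes of one species matching, or a mixed
    column).

Matching is residue identity by default; an alternative mode treats
residues in the same physicochemical group as matching, which is the mode
relevant to percent *similarity* figures.  A gap never matches anything.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum

from .errors import (
    AlignmentError,
    AlphabetError,
    MalformedColumnError,
    UndefinedSimilarityError,
)

GAP = "-"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
_LEGAL = AMINO_ACIDS | {GAP, "X"}  # X = unknown residue; matches nothing


class SeqRole(str, Enum):
    """The five roles of a subfamily alignment row."""

    OUTGROUP = "OUTGROUP"
    S1_A = "S1_A"  # species-1 paralogue a (chick "a" in the study)
    S1_B = "S1_B"
    S2_A = "S2_A"  # species-2 paralogue a (mouse "a")
    S2_B = "S2_B"

    @property
    def is_vertebrate(self) -> bool:
        return self is not SeqRole.OUTGROUP


VERTEBRATE_ROLES: tuple[SeqRole, ...] = (
    SeqRole.S1_A,
    SeqRole.S1_B,
    SeqRole.S2_A,
    SeqRole.S2_B,
)

A_ROLES = frozenset({SeqRole.S1_A, SeqRole.S2_A})
B_ROLES = frozenset({SeqRole.S1_B, SeqRole.S2_B})


class Category(str, Enum):
    """Conservation category of one alignment column."""

    CONSERVED_CYS = "CONSERVED_CYS"
    FULLY_CONSERVED = "FULLY_CONSERVED"
    SINGLE_GENE_DIVERGENT = "SINGLE_GENE_DIVERGENT"
    PARALOGUE_A_CONSERVED = "PARALOGUE_A_CONSERVED"
    PARALOGUE_B_CONSERVED = "PARALOGUE_B_CONSERVED"
    VERTEBRATE_ONLY = "VERTEBRATE_ONLY"
    OUTGROUP_GAP = "OUTGROUP_GAP"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ColumnClass:
    """Category of a column, plus the divergent gene where applicable."""

    category: Category
    divergent_role: SeqRole | None = None

    def __post_init__(self) -> None:
        if self.category is not Category.SINGLE_GENE_DIVERGENT:
            if self.divergent_role is not None:
                raise ValueError(
                    "divergent_role is only meaningful for "
                    "SINGLE_GENE_DIVERGENT columns"
                )
        elif self.divergent_role is None or not self.divergent_role.is_vertebrate:
            raise ValueError(
                "SINGLE_GENE_DIVERGENT requires a vertebrate divergent_role"
            )


class MatchMode(str, Enum):
    IDENTITY = "IDENTITY"
    SIMILARITY_GROUPS = "SIMILARITY_GROUPS"


#: Disjoint physicochemical amino-acid groups used by the default
#: SIMILARITY_GROUPS policy: aliphatic, aromatic, basic, acidic, amide,
#: hydroxyl, and the three singletons C, G, P that behave like no other
#: residue.  (The familiar Clustal "strong groups" are not usable here
#: because they overlap; a residue must belong to at most one group.)
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("AVLIM"),
    frozenset("FWY"),
    frozenset("KRH"),
    frozenset("DE"),
    frozenset("NQ"),
    frozenset("ST"),
    frozenset("C"),
    frozenset("G"),
    frozenset("P"),
)


@dataclass(frozen=True)
class MatchPolicy:
    """Decides whether two residues count as conserved.

    IDENTITY mode requires equal letters.  SIMILARITY_GROUPS mode also
    accepts two residues from the same group.  Gaps and 'X' never match.
    """

    mode: MatchMode = MatchMode.IDENTITY
    similarity_groups: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_GROUPS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.similarity_groups:
            if seen & group:
                raise ValueError(
                    f"similarity groups overlap on {sorted(seen & group)}"
                )
            seen |= group

    def group_of(self, residue: str) -> frozenset[str] | None:
        for group in self.similarity_groups:
            if residue in group:
                return group
        return None

    def matches(self, a: str, b: str) -> bool:
        if a == GAP or b == GAP or a == "X" or b == "X":
            return False
        if a == b:
            return True
        if self.mode is MatchMode.SIMILARITY_GROUPS:
            g = self.group_of(a)
            return g is not None and b in g
        return False


IDENTITY_POLICY = MatchPolicy(MatchMode.IDENTITY)
SIMILARITY_POLICY = MatchPolicy(MatchMode.SIMILARITY_GROUPS)


@dataclass
class SubfamilyAlignment:
    """Five role-tagged aligned protein sequences of one subfamily.

    ``rows`` maps each :class:`SeqRole` to ``(label, residues)`` where
    ``label`` is the sequence name from the source file.
    """

    subfamily_name: str
    rows: dict[SeqRole, tuple[str, str]]

    def __post_init__(self) -> None:
        if set(self.rows) != set(SeqRole):
            missing = sorted(r.value for r in set(SeqRole) - set(self.rows))
            raise AlignmentError(
                f"alignment {self.subfamily_name!r} missing roles: {missing}"
            )
        lengths = {len(seq) for _, seq in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"alignment {self.subfamily_name!r} has ragged rows "
                f"(lengths {sorted(lengths)})"
            )
        if next(iter(lengths)) == 0:
            raise AlignmentError(f"alignment {self.subfamily_name!r} is empty")
        for role, (label, seq) in self.rows.items():
            bad = set(seq.upper()) - _LEGAL
            if bad:
                raise AlphabetError(
                    f"sequence {label!r} ({role.value}) contains illegal "
                    f"characters {sorted(bad)}"
                )
            self.rows[role] = (label, seq.upper())
        for i in range(self.length):
            if all(seq[i] == GAP for _, seq in self.rows.values()):
                raise AlignmentError(
                    f"alignment {self.subfamily_name!r}: column {i + 1} is "
                    "all-gap"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))[1])

    def column(self, index: int) -> dict[SeqRole, str]:
        """Residues of 0-based column ``index``, keyed by role."""
        return {role: seq[index] for role, (_, seq) in self.rows.items()}

    def columns(self) -> Iterable[dict[SeqRole, str]]:
        for i in range(self.length):
            yield self.column(i)


def classify_column(
    column: Mapping[SeqRole, str], policy: MatchPolicy = IDENTITY_POLICY
) -> ColumnClass:
    """Classify one alignment column.

    The decision tree is evaluated in priority order: outgroup gap, then
    the all-cysteine rule, then the match-set rules keyed on which
    vertebrate roles carry the outgroup residue.
    """
    if set(column) != set(SeqRole):
        missing = sorted(r.value for r in set(SeqRole) - set(column))
        raise MalformedColumnError(f"column missing roles: {missing}")
    for role, res in column.items():
        if res not in _LEGAL:
            raise AlphabetError(
                f"illegal residue {res!r} for role {role.value}"
            )

    out = column[SeqRole.OUTGROUP]
    if out == GAP:
        return ColumnClass(Category.OUTGROUP_GAP)
    if all(column[r] == "C" for r in SeqRole):
        return ColumnClass(Category.CONSERVED_CYS)

    matching = frozenset(
        r for r in VERTEBRATE_ROLES if policy.matches(column[r], out)
    )
    if len(matching) == 4:
        return ColumnClass(Category.FULLY_CONSERVED)
    if len(matching) == 3:
        (odd,) = set(VERTEBRATE_ROLES) - matching
        return ColumnClass(Category.SINGLE_GENE_DIVERGENT, divergent_role=odd)
    if matching == A_ROLES:
        return ColumnClass(Category.PARALOGUE_A_CONSERVED)
    if matching == B_ROLES:
        return ColumnClass(Category.PARALOGUE_B_CONSERVED)
    if not matching:
        verts = [column[r] for r in VERTEBRATE_ROLES]
        if GAP not in verts and len(set(verts)) == 1:
            return ColumnClass(Category.VERTEBRATE_ONLY)
    return ColumnClass(Category.UNCLASSIFIED)


def pairwise_similarity(
    aln: SubfamilyAlignment,
    role: SeqRole,
    policy: MatchPolicy = IDENTITY_POLICY,
) -> float:
    """Percent of mutually ungapped columns where ``role`` matches the
    outgroup under ``policy``.

    The denominator counts columns where both the outgroup and the chosen
    sequence carry a residue; columns gapped in either are ignored, so the
    value reflects substitution rather than indel history.
    """
    if role is SeqRole.OUTGROUP:
        raise ValueError("similarity to the outgroup itself is undefined")
    out_seq = aln.rows[SeqRole.OUTGROUP][1]
    seq = aln.rows[role][1]
    both = [
        (o, r) for o, r in zip(out_seq, seq) if o != GAP and r != GAP
    ]
    if not both:
        raise UndefinedSimilarityError(
            f"no mutually ungapped columns between {role.value} and the "
            "outgroup"
        )
    n_match = sum(policy.matches(o, r) for o, r in both)
    return 100.0 * n_match / len(both)


@dataclass
class ConservationProfile:
    """Per-column classes and their summary counts for one subfamily."""

    subfamily_name: str
    column_classes: list[ColumnClass]
    n_conserved_cys: int
    n_fully_conserved: int
    n_paralogue_a_specific: int
    n_paralogue_b_specific: int
    single_gene_divergence: dict[SeqRole, int]
    pairwise_similarity: dict[SeqRole, float]
    match_mode: MatchMode

    def category_counts(self) -> dict[Category, int]:
        counts = {cat: 0 for cat in Category}
        for cc in self.column_classes:
            counts[cc.category] += 1
        return counts

    def to_dict(self) -> dict:
        """JSON-ready representation."""
        return {
            "subfamily_name": self.subfamily_name,
            "n_columns": len(self.column_classes),
            "match_mode": self.match_mode.value,
            "n_conserved_cys": self.n_conserved_cys,
            "n_fully_conserved": self.n_fully_conserved,
            "n_paralogue_a_specific": self.n_paralogue_a_specific,
            "n_paralogue_b_specific": self.n_paralogue_b_specific,
            "single_gene_divergence": {
                r.value: n for r, n in sorted(self.single_gene_divergence.items())
            },
            "pairwise_similarity": {
                r.value: round(s, 4)
                for r, s in sorted(self.pairwise_similarity.items())
            },
            "category_counts": {
                c.value: n for c, n in self.category_counts().items()
            },
        }


def profile_alignment(
    aln: SubfamilyAlignment, policy: MatchPolicy = IDENTITY_POLICY
) -> ConservationProfile:
    """Classify every column and aggregate the subfamily-level summary."""
    classes = [classify_column(col, policy) for col in aln.columns()]
    sgd: dict[SeqRole, int] = {r: 0 for r in VERTEBRATE_ROLES}
    for cc in classes:
        if cc.category is Category.SINGLE_GENE_DIVERGENT:
            assert cc.divergent_role is not None
            sgd[cc.divergent_role] += 1
    counts = {cat: 0 for cat in Category}
    for cc in classes:
        counts[cc.category] += 1
    sims = {
        role: pairwise_similarity(aln, role, policy)
        for role in VERTEBRATE_ROLES
    }
    return ConservationProfile(
        subfamily_name=aln.subfamily_name,
        column_classes=classes,
        n_conserved_cys=counts[Category.CONSERVED_CYS],
        n_fully_conserved=counts[Category.FULLY_CONSERVED],
        n_paralogue_a_specific=counts[Category.PARALOGUE_A_CONSERVED],
        n_paralogue_b_specific=counts[Category.PARALOGUE_B_CONSERVED],
        single_gene_divergence=sgd,
        pairwise_similarity=sims,
        match_mode=policy.mode,
    )
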