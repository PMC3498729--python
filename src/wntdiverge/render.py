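"""Text renderers for the three summary views, plus the grid parser.

The comparison grid uses the literal ordinal symbols (=, *, **, ***; '.'
for not-applicable) so rendered output can be read side by side with the
published-style summary figures.
"""

from __future__ import annotations

from .expression import (
    ComparisonKind,
    ComparisonResult,
    SimilarityGrade,
    SYMBOL_TO_GRADE,
)
from .errors import ValidationError
from .msa import ConservationProfile
from .sharing import TerritorySharingReport

_KIND_ORDER = (
    ComparisonKind.PARALOGUES_SPECIES1,
    ComparisonKind.PARALOGUES_SPECIES2,
    ComparisonKind.ORTHOLOGUES_A,
    ComparisonKind.ORTHOLOGUES_B,
)


def render_comparison_grid(result: ComparisonResult) -> str:
    """TSV: one territory per row, one ordinal symbol per comparison kind."""
    header = ["territory"] + [k.value for k in _KIND_ORDER]
    lines = ["\t".join(header)]
    for tid in result.territory_order:
        cells = [
            result.grid.get(
                (tid, kind), SimilarityGrade.NOT_APPLICABLE
            ).symbol
            for kind in _KIND_ORDER
        ]
        lines.append("\t".join([tid, *cells]))
    return "\n".join(lines) + "\n"


def parse_comparison_grid(
    text: str,
) -> tuple[list[str], dict[tuple[str, ComparisonKind], SimilarityGrade]]:
    """Inverse of :func:`render_comparison_grid`: territory order plus grid."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValidationError("empty grid table")
    header = lines[0].split("\t")
    try:
        kinds = [ComparisonKind(h) for h in header[1:]]
    except ValueError as exc:
        raise ValidationError(f"bad grid header: {exc}") from exc
    order: list[str] = []
    grid: dict[tuple[str, ComparisonKind], SimilarityGrade] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ValidationError(f"malformed grid row: {ln!r}")
        tid = parts[0]
        order.append(tid)
        for kind, symbol in zip(kinds, parts[1:]):
            if symbol not in SYMBOL_TO_GRADE:
                raise ValidationError(f"unknown grade symbol {symbol!r}")
            grid[(tid, kind)] = SYMBOL_TO_GRADE[symbol]
    return order, grid


def render_profile_summary(profile: ConservationProfile) -> str:
    """Subfamily summary: cysteines, paralogue-specific sites, single-gene
    divergence per gene, percent similarity to the outgroup per gene."""
    lines = [
        f"subfamily\t{profile.subfamily_name}",
        f"n_columns\t{len(profile.column_classes)}",
        f"match_mode\t{profile.match_mode.value}",
        f"conserved_cysteines\t{profile.n_conserved_cys}",
        f"paralogue_a_specific_sites\t{profile.n_paralogue_a_specific}",
        f"paralogue_b_specific_sites\t{profile.n_paralogue_b_specific}",
    ]
    for role, n in sorted(profile.single_gene_divergence.items()):
        lines.append(f"single_gene_divergence[{role.value}]\t{n}")
    for role, s in sorted(profile.pairwise_similarity.items()):
        lines.append(f"similarity_vs_outgroup[{role.value}]\t{s:.1f}")
    return "\n".join(lines) + "\n"


def render_column_classes(profile: ConservationProfile) -> str:
    """Per-column TSV (1-based index, category, divergent role)."""
    lines = ["column\tcategory\tdivergent_role"]
    for i, cc in enumerate(profile.column_classes, start=1):
        divergent = cc.divergent_role.value if cc.divergent_role else "."
        lines.append(f"{i}\t{cc.category.value}\t{divergent}")
    return "\n".join(lines) + "\n"


def render_sharing_report(report: TerritorySharingReport) -> str:
    """TSV mirroring the shared-territories table: territory, partners,
    R/NR flag; excluded territories are listed at the end."""
    lines = ["territory\tshared_with\treciprocal"]
    for tid, row in report.rows.items():
        partners = ",".join(row.shared_with) if row.shared_with else "."
        lines.append(f"{tid}\t{partners}\t{row.flag}")
    for tid in report.excluded:
        lines.append(f"{tid}\t.\texcluded")
    return "\n".join(lines) + "\n"
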