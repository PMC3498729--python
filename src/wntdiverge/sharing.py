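"""Subset/reciprocity structure of a binary gene x territory matrix.

For each territory t let S(t) be its expressing-gene set.  Territory t
"shares" with t' when S(t) is contained in S(t'): every gene active in t is
also active in t'.  A row is *reciprocal* (R) when every listed partner has
exactly the same gene set — sharing runs both ways for all of them —
otherwise not reciprocal (NR).  Non-reciprocal sharing is the common case
in the Wnt data and argues for territory-by-territory regulation rather
than a single shared regulatory module.

Territories with no expressing gene are excluded from the report (they
would vacuously share with everything) and listed separately.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError, VocabularyError


@dataclass
class SharingRow:
    territory_id: str
    shared_with: list[str]
    reciprocal: bool
    #: partners whose gene set equals S(t) exactly (pair-level reciprocity)
    equal_set_partners: list[str] = field(default_factory=list)

    @property
    def flag(self) -> str:
        return "R" if self.reciprocal else "NR"


@dataclass
class TerritorySharingReport:
    rows: dict[str, SharingRow]
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rows": {
                tid: {
                    "shared_with": row.shared_with,
                    "reciprocal": row.flag,
                    "equal_set_partners": row.equal_set_partners,
                }
                for tid, row in self.rows.items()
            },
            "excluded": list(self.excluded),
        }


def _validate_binary(matrix: pd.DataFrame) -> None:
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValidationError("presence matrix needs >=1 gene and >=1 territory")
    values = matrix.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise ValidationError("presence matrix entries must be 0 or 1")


def gene_sets(matrix: pd.DataFrame) -> dict[str, frozenset[str]]:
    """S(t): the expressing-gene set of each territory (column)."""
    _validate_binary(matrix)
    return {
        str(t): frozenset(matrix.index[matrix[t] == 1])
        for t in matrix.columns
    }


def shared_territories(matrix: pd.DataFrame) -> TerritorySharingReport:
    """Per-territory containment lists and R/NR flags.

    Output order follows the matrix's column (vocabulary) order; a
    territory never lists itself.
    """
    sets = gene_sets(matrix)
    order = [str(t) for t in matrix.columns]
    rows: dict[str, SharingRow] = {}
    excluded: list[str] = []
    for t in order:
        if not sets[t]:
            excluded.append(t)
            continue
        partners = [
            u for u in order if u != t and sets[t] <= sets[u]
        ]
        # vacuously R when nothing contains S(t): no one-way sharing exists
        reciprocal = all(sets[u] == sets[t] for u in partners)
        equal = [u for u in partners if sets[u] == sets[t]]
        rows[t] = SharingRow(t, partners, reciprocal, equal)
    return TerritorySharingReport(rows=rows, excluded=excluded)


def universal_superset_check(
    matrix: pd.DataFrame, group: Sequence[str], target: str
) -> bool:
    """True iff every gene expressed anywhere in ``group`` is also
    expressed in ``target`` (e.g. "expression anywhere in the CNS is shared
    with the mesencephalon")."""
    if not group:
        raise ValidationError("group must be non-empty")
    sets = gene_sets(matrix)
    unknown = [t for t in [*group, target] if t not in sets]
    if unknown:
        raise VocabularyError(f"unknown territory ids: {unknown}")
    pooled: set[str] = set()
    for t in group:
        pooled |= sets[t]
    return pooled <= sets[target]
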