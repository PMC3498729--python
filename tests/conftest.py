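"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive the decision rules as flat nested
conditionals with their own residue matching, so agreement with the
package is a two-route check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wntdiverge.expression import (
    ExpressionAnnotation,
    GeneId,
    ParalogueTag,
    Territory,
)
from wntdiverge.msa import GAP, Category, SeqRole, SubfamilyAlignment
from wntdiverge.vocab import CHICK, DEFAULT_STAGE_MAP, MOUSE

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# oracle: column classification (identity matching only)


def oracle_classify(column: dict[SeqRole, str]) -> tuple[str, SeqRole | None]:
    """Brute-force re-derivation of the column decision tree.

    Returns (category name, divergent role or None).
    """
    a = column[SeqRole.OUTGROUP]
    ca = column[SeqRole.S1_A]
    cb = column[SeqRole.S1_B]
    ma = column[SeqRole.S2_A]
    mb = column[SeqRole.S2_B]
    if a == GAP:
        return "OUTGROUP_GAP", None
    if a == "C" and ca == "C" and cb == "C" and ma == "C" and mb == "C":
        return "CONSERVED_CYS", None
    hits = []
    for role, res in (
        (SeqRole.S1_A, ca),
        (SeqRole.S1_B, cb),
        (SeqRole.S2_A, ma),
        (SeqRole.S2_B, mb),
    ):
        if res != GAP and res == a:
            hits.append(role)
    if len(hits) == 4:
        return "FULLY_CONSERVED", None
    if len(hits) == 3:
        for role in (SeqRole.S1_A, SeqRole.S1_B, SeqRole.S2_A, SeqRole.S2_B):
            if role not in hits:
                return "SINGLE_GENE_DIVERGENT", role
    if len(hits) == 2 and SeqRole.S1_A in hits and SeqRole.S2_A in hits:
        return "PARALOGUE_A_CONSERVED", None
    if len(hits) == 2 and SeqRole.S1_B in hits and SeqRole.S2_B in hits:
        return "PARALOGUE_B_CONSERVED", None
    if len(hits) == 0:
        if (
            GAP not in (ca, cb, ma, mb)
            and ca == cb == ma == mb
        ):
            return "VERTEBRATE_ONLY", None
    return "UNCLASSIFIED", None


def random_column(rng: np.random.Generator, p_gap: float = 0.1) -> dict[SeqRole, str]:
    """A random 5-residue column; biased so interesting categories occur."""
    letters = AA20 + "C" * 6  # enrich cysteine so CONSERVED_CYS appears
    col = {}
    base = letters[rng.integers(len(letters))]
    for role in SeqRole:
        if rng.random() < p_gap:
            col[role] = GAP
        elif rng.random() < 0.55:
            col[role] = base  # correlated residues -> conserved-ish columns
        else:
            col[role] = letters[rng.integers(len(letters))]
    if all(v == GAP for v in col.values()):
        col[SeqRole.S1_A] = base
    return col


# ---------------------------------------------------------------------------
# oracle: territory sharing


def oracle_sharing(matrix: pd.DataFrame) -> dict:
    """Direct double-loop subset test over all ordered territory pairs."""
    sets = {
        t: {g for g in matrix.index if matrix.loc[g, t] == 1}
        for t in matrix.columns
    }
    rows = {}
    excluded = []
    for t in matrix.columns:
        if not sets[t]:
            excluded.append(t)
            continue
        partners = []
        for u in matrix.columns:
            if u == t:
                continue
            if all(g in sets[u] for g in sets[t]):
                partners.append(u)
        rows[t] = (partners, all(sets[u] == sets[t] for u in partners))
    return {"rows": rows, "excluded": excluded}


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_alignment() -> SubfamilyAlignment:
    """Six hand-classified columns: cysteine, single-gene divergence (x2),
    a-paralogue conservation, vertebrate-only, outgroup gap."""
    return SubfamilyAlignment(
        subfamily_name="toy",
        rows={
            SeqRole.OUTGROUP: ("amphi", "CKGT-A"),
            SeqRole.S1_A: ("chick_a", "CKGNLA"),
            SeqRole.S1_B: ("chick_b", "CKSNLA"),
            SeqRole.S2_A: ("mouse_a", "CKGNLA"),
            SeqRole.S2_B: ("mouse_b", "CRSNLV"),
        },
    )


def _gene(subfamily: str, tag: str, species: str) -> GeneId:
    return GeneId(subfamily, ParalogueTag(tag), species)


@pytest.fixture
def limb_annotations() -> list[ExpressionAnnotation]:
    """The limb-ectoderm pattern of the Wnt7 pair: the a-paralogue in
    dorsal ectoderm and the b-paralogue in proximoventral ectoderm, in both
    species and at every stage."""
    annotations = []
    for species in (MOUSE, CHICK):
        for stage in DEFAULT_STAGE_MAP.stages_for(species):
            annotations.append(
                ExpressionAnnotation(
                    gene=_gene("Wnt7", "A", species),
                    stage=stage,
                    territory_id="limb_ectoderm",
                    domains=frozenset({"dorsal_ectoderm"}),
                )
            )
            annotations.append(
                ExpressionAnnotation(
                    gene=_gene("Wnt7", "B", species),
                    stage=stage,
                    territory_id="limb_ectoderm",
                    domains=frozenset({"proximoventral_ectoderm"}),
                )
            )
    return annotations


@pytest.fixture
def limb_territories() -> list[Territory]:
    return [Territory("limb_ectoderm", "limb ectoderm", None)]


@pytest.fixture
def sharing_example_matrix() -> pd.DataFrame:
    """The package's hand-built qualitative sharing fixture (synthetic; not
    a cell-for-cell copy of any published matrix)."""
    from wntdiverge.datasets import qualitative_sharing_matrix

    return qualitative_sharing_matrix()


from wntdiverge.datasets import CNS_GROUP  # noqa: E402  (re-export for tests)
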