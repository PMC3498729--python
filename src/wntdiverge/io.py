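"""Readers and writers for the package's file formats.

Alignments come in as aligned FASTA or Clustal (via Bio.AlignIO) with a
role-map sidecar binding sequence labels to the five alignment roles.
Tabular data (annotations, territory vocabulary, stage map, presence
matrix) are plain TSV; structured results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import AlignIO

from .errors import (
    AlignmentError,
    InputOutputError,
    ValidationError,
)
from .expression import (
    ExpressionAnnotation,
    GeneId,
    Level,
    ParalogueTag,
    StageMap,
    Territory,
)
from .msa import SeqRole, SubfamilyAlignment
from .simulate import TruthGrid

# ---------------------------------------------------------------------------
# alignments


def _alignment_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".faa", ".mfa"}:
        return "fasta"
    if suffix in {".aln", ".clustal", ".clw"}:
        return "clustal"
    raise InputOutputError(
        f"cannot infer alignment format from {path.name!r} "
        "(use .fasta/.fa or .aln/.clustal)"
    )


def read_role_map(path: str | Path) -> dict[str, SeqRole]:
    """TSV sidecar: two columns, sequence label and role name."""
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"role map not found: {path}")
    mapping: dict[str, SeqRole] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{path.name}:{lineno}: expected 'label<TAB>role'"
            )
        label, role_name = parts
        try:
            role = SeqRole(role_name.strip().upper())
        except ValueError as exc:
            raise ValidationError(
                f"{path.name}:{lineno}: unknown role {role_name!r}"
            ) from exc
        if role in mapping.values():
            raise ValidationError(
                f"{path.name}:{lineno}: role {role.value} assigned twice"
            )
        mapping[label.strip()] = role
    if len(mapping) != len(SeqRole):
        raise ValidationError(
            f"{path.name}: role map must bind exactly {len(SeqRole)} labels"
        )
    return mapping


def read_alignment(
    alignment_path: str | Path,
    role_map: dict[str, SeqRole] | str | Path,
    subfamily_name: str | None = None,
    fmt: str | None = None,
) -> SubfamilyAlignment:
    """Load a five-sequence subfamily alignment and tag rows with roles."""
    path = Path(alignment_path)
    if not path.exists():
        raise InputOutputError(f"alignment not found: {path}")
    if not isinstance(role_map, dict):
        role_map = read_role_map(role_map)
    fmt = fmt or _alignment_format(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path.name}: {exc}") from exc
    rows: dict[SeqRole, tuple[str, str]] = {}
    for record in msa:
        if record.id not in role_map:
            raise ValidationError(
                f"sequence {record.id!r} has no role assignment"
            )
        role = role_map[record.id]
        if role in rows:
            raise AlignmentError(f"role {role.value} appears twice")
        rows[role] = (record.id, str(record.seq).upper())
    return SubfamilyAlignment(
        subfamily_name=subfamily_name or path.stem, rows=rows
    )


def write_alignment_fasta(aln: SubfamilyAlignment, path: str | Path) -> None:
    """Aligned FASTA in fixed role order; byte-stable for a given alignment."""
    order = [SeqRole.OUTGROUP, SeqRole.S1_A, SeqRole.S1_B, SeqRole.S2_A, SeqRole.S2_B]
    lines = []
    for role in order:
        label, seq = aln.rows[role]
        lines.append(f">{label}")
        for i in range(0, len(seq), 60):
            lines.append(seq[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def write_role_map(aln: SubfamilyAlignment, path: str | Path) -> None:
    lines = [
        f"{label}\t{role.value}"
        for role, (label, _) in sorted(aln.rows.items(), key=lambda kv: kv[0].value)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tables

_ANNOTATION_COLUMNS = [
    "gene",
    "species",
    "subfamily",
    "paralogue_tag",
    "stage",
    "territory_id",
    "domains",
    "level",
]


def write_annotations(
    annotations: list[ExpressionAnnotation], path: str | Path
) -> None:
    records = [
        {
            "gene": a.gene.key,
            "species": a.gene.species,
            "subfamily": a.gene.subfamily,
            "paralogue_tag": a.gene.paralogue_tag.value,
            "stage": a.stage,
            "territory_id": a.territory_id,
            "domains": ";".join(sorted(a.domains)),
            "level": a.level.value if a.level else "",
        }
        for a in annotations
    ]
    pd.DataFrame(records, columns=_ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> list[ExpressionAnnotation]:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"annotation table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_ANNOTATION_COLUMNS) - {"gene", "level"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path.name}: missing columns {sorted(missing)}"
        )
    out: list[ExpressionAnnotation] = []
    for i, row in df.iterrows():
        try:
            gene = GeneId(
                subfamily=row["subfamily"],
                paralogue_tag=ParalogueTag(row["paralogue_tag"]),
                species=row["species"],
            )
            domains = frozenset(
                d for d in str(row["domains"]).split(";") if d
            )
            level = (
                Level(row["level"]) if row.get("level", "") else None
            )
            out.append(
                ExpressionAnnotation(
                    gene=gene,
                    stage=row["stage"],
                    territory_id=row["territory_id"],
                    domains=domains,
                    level=level,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValidationError(
                f"{path.name}: bad annotation at row {i + 2}: {exc}"
            ) from exc
    return out


def write_territories(territories: list[Territory], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"id": t.id, "name": t.name, "parent_id": t.parent_id or ""}
            for t in territories
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_territories(path: str | Path) -> list[Territory]:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"territory vocabulary not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    territories = [
        Territory(row["id"], row["name"], row["parent_id"] or None)
        for _, row in df.iterrows()
    ]
    ids = [t.id for t in territories]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path.name}: duplicate territory ids")
    return territories


def write_stage_map(stage_map: StageMap, path: str | Path) -> None:
    lines = [f"{stage_map.species1}\t{stage_map.species2}"]
    lines += [f"{a}\t{b}" for a, b in stage_map.pairs]
    Path(path).write_text("\n".join(lines) + "\n")


def read_stage_map(path: str | Path) -> StageMap:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"stage map not found: {path}")
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip()
    ]
    if len(lines) < 2:
        raise ValidationError(f"{path.name}: need a header and >=1 pair")
    header = lines[0].split("\t")
    if len(header) != 2:
        raise ValidationError(f"{path.name}: header must name two species")
    pairs = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path.name}: malformed stage pair {ln!r}")
        pairs.append((parts[0], parts[1]))
    return StageMap(species1=header[0], species2=header[1], pairs=tuple(pairs))


def write_presence_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"presence matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not df.map(lambda v: v in (0, 1)).all().all():
        raise ValidationError(f"{path.name}: entries must be 0 or 1")
    return df.astype(int)


# ---------------------------------------------------------------------------
# truth / JSON helpers


def write_truth(truth: TruthGrid, path: str | Path) -> None:
    payload = {
        subfamily: {
            f"{tid}|{kind.value}": grade.symbol
            for (tid, kind), grade in cells.items()
        }
        for subfamily, cells in truth.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> TruthGrid:
    from .expression import ComparisonKind, SYMBOL_TO_GRADE

    raw = json.loads(Path(path).read_text())
    truth: TruthGrid = {}
    for subfamily, cells in raw.items():
        truth[subfamily] = {}
        for key, symbol in cells.items():
            tid, kind = key.rsplit("|", 1)
            truth[subfamily][(tid, ComparisonKind(kind))] = SYMBOL_TO_GRADE[
                symbol
            ]
    return truth


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
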