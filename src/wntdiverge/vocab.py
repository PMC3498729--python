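"""Default controlled vocabularies: embryonic territories and the
mouse/chick stage correspondence.

The territory list covers the mid-embryogenesis anatomy used to tabulate
Wnt expression: CNS subdivisions (grouped under ``cns``), branchial arches
1–4, limb ectoderm/mesenchyme, facial structures, sensory placodes, gut,
heart, lung, somites, tail bud, body wall and the genitourinary system.
Datasets are free to supply their own vocabulary file; this one is the
package default for simulation and examples.
"""

from __future__ import annotations

from .expression import StageMap, Territory

MOUSE = "mouse"
CHICK = "chick"

#: Theiler (mouse) vs Hamburger–Hamilton (chick) stages at which overall
#: limb morphology is comparable.
DEFAULT_STAGE_MAP = StageMap(
    species1=MOUSE,
    species2=CHICK,
    pairs=(("TS15", "HH20"), ("TS17", "HH23"), ("TS19", "HH26")),
)

DEFAULT_TERRITORIES: tuple[Territory, ...] = (
    Territory("cns", "central nervous system", None),
    Territory("telencephalon", "telencephalon", "cns"),
    Territory("diencephalon", "diencephalon", "cns"),
    Territory("mesencephalon", "mesencephalon", "cns"),
    Territory("rhombencephalon", "rhombencephalon", "cns"),
    Territory("neural_tube", "neural tube", "cns"),
    Territory("eye", "eye", None),
    Territory("otic_vesicle", "otic vesicle", None),
    Territory("frontonasal_process", "frontonasal process", None),
    Territory("branchial_arch_1", "branchial arch 1", None),
    Territory("branchial_arch_2", "branchial arch 2", None),
    Territory("branchial_arch_3", "branchial arch 3", None),
    Territory("branchial_arch_4", "branchial arch 4", None),
    Territory("limb_ectoderm", "limb ectoderm", None),
    Territory("limb_mesenchyme", "limb mesenchyme", None),
    Territory("heart", "heart", None),
    Territory("lung", "lung", None),
    Territory("foregut", "foregut", None),
    Territory("hindgut", "hindgut", None),
    Territory("body_wall", "body wall", None),
    Territory("somites", "somites", None),
    Territory("tail_bud", "tail bud", None),
    Territory("genitourinary", "genitourinary system", None),
)

#: CNS subdivisions proper (the grouping node itself is not a territory in
#: which expression is annotated).
CNS_TERRITORIES: tuple[str, ...] = tuple(
    t.id for t in DEFAULT_TERRITORIES if t.parent_id == "cns"
)

#: Candidate subdomain labels per territory used by the expression
#: simulator; loosely modelled on the kinds of domains annotated for limb
#: and brain territories.
DEFAULT_DOMAIN_POOL: tuple[str, ...] = (
    "dorsal",
    "ventral",
    "proximal",
    "distal",
    "anterior",
    "posterior",
    "medial",
    "lateral",
    "midline",
    "epithelium",
    "mesenchyme",
    "roof",
    "floor",
)

DEFAULT_SUBFAMILIES: tuple[str, ...] = ("Wnt2", "Wnt5", "Wnt7", "Wnt8")
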