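"""Small built-in example datasets (synthetic, hand-built).

These encode qualitative structure for demonstration and testing; none is
a cell-for-cell copy of any published data matrix.
"""

from __future__ import annotations

import pandas as pd

#: CNS subdivisions used by the qualitative sharing example.
CNS_GROUP: tuple[str, ...] = (
    "telencephalon",
    "diencephalon",
    "mesencephalon",
    "rhombencephalon",
    "neural_tube",
)


def qualitative_sharing_matrix() -> pd.DataFrame:
    """Synthetic 8-gene presence matrix with the qualitative
    territory-sharing structure seen in the Wnt dataset:

    * every gene expressed anywhere in the CNS is also expressed in the
      mesencephalon (a universally shared CNS territory);
    * branchial arches 1 and 2 express identical gene sets, as do arches
      3 and 4, and each arch pair's set is contained nowhere else, so the
      arch pairs are the only reciprocal rows;
    * the limb ectoderm's genes are a strict subset of the
      mesencephalon's (one-way, non-reciprocal sharing);
    * the heart expresses none of the genes (excluded territory).
    """
    territories = [
        *CNS_GROUP,
        "branchial_arch_1",
        "branchial_arch_2",
        "branchial_arch_3",
        "branchial_arch_4",
        "limb_ectoderm",
        "heart",
    ]
    sets: dict[str, set[str]] = {
        "telencephalon": {"g1", "g2"},
        "diencephalon": {"g1", "g3"},
        "mesencephalon": {"g1", "g2", "g3", "g4", "g5", "g6"},
        "rhombencephalon": {"g2", "g3", "g4"},
        "neural_tube": {"g3", "g4"},
        "branchial_arch_1": {"g1", "g2", "g7"},
        "branchial_arch_2": {"g1", "g2", "g7"},
        "branchial_arch_3": {"g3", "g7", "g8"},
        "branchial_arch_4": {"g3", "g7", "g8"},
        "limb_ectoderm": {"g1", "g2", "g3", "g4", "g5"},
        "heart": set(),
    }
    genes = [f"g{i}" for i in range(1, 9)]
    matrix = pd.DataFrame(0, index=genes, columns=territories, dtype=int)
    for territory, members in sets.items():
        for g in members:
            matrix.loc[g, territory] = 1
    return matrix
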