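"""Named study fixtures: the tetrapod skipping tree and the species table.

Both are synthetic encodings of a cross-vertebrate survey design: a rooted
20-tip tetrapod tree (plus a lungfish-grade outgroup tip) carrying the
short-isoform presence/absence character, and a 29-species status table
(the 20 tree taxa plus nine ray-finned fish and outgroup species, all
short-isoform negative) used to parameterise the read simulator.  Species
codes are three/four-letter binomen abbreviations.
"""

from __future__ import annotations

import pandas as pd

from .parsimony import TipStateTree

__all__ = [
    "TETRAPOD_TREE_NEWICK",
    "TETRAPOD_SKIPPING_PRESENT",
    "tetrapod_skipping_fixture",
    "species_status_table",
]

#: Rooted tetrapod topology: amphibians + coelacanth/lungfish grade sister to
#: (mammals, (squamates, (turtles + archosaurs))).
TETRAPOD_TREE_NEWICK = (
    "((Nvi,((Xtr,Xla),(Lca,Lpi))),"
    "((Oan,(Pci,(Clu,(Mmu,Hsa)))),"
    "((Aca,Pvi),((Cpi,Psi),(Sca,(Apl,(Gga,(Tgu,(Fal,Pmaj)))))))));"
)

#: Tips where exon skipping (the short isoform) was scored present.
TETRAPOD_SKIPPING_PRESENT = frozenset(
    {"Lca", "Lpi", "Aca", "Pvi", "Apl", "Gga", "Tgu", "Fal", "Pmaj",
     "Clu", "Mmu", "Hsa"}
)

_TETRAPOD_TIPS = (
    "Nvi", "Xtr", "Xla", "Lca", "Lpi",
    "Oan", "Pci", "Clu", "Mmu", "Hsa",
    "Aca", "Pvi", "Cpi", "Psi", "Sca",
    "Apl", "Gga", "Tgu", "Fal", "Pmaj",
)

#: Ray-finned fish / outgroup species of the survey; none expressed the
#: short isoform in brain libraries.
_FISH_SPECIES = ("Dre", "Cau", "Ame", "Cse", "Pre", "Ssa", "Loc", "Cmi", "Pmar")


def tetrapod_skipping_fixture() -> TipStateTree:
    """The 20-tip tree with short-isoform presence states at the tips."""
    states = {
        tip: tip in TETRAPOD_SKIPPING_PRESENT for tip in _TETRAPOD_TIPS
    }
    return TipStateTree.from_newick(TETRAPOD_TREE_NEWICK, states)


def species_status_table() -> pd.DataFrame:
    """29-row survey design: species, short-isoform status, depth tier.

    Depth tiers are assigned by cycling low/medium/high down the species
    list, deliberately uncorrelated with isoform status so that the depth
    report's association diagnostic has nothing to find.
    """
    species = list(_TETRAPOD_TIPS) + list(_FISH_SPECIES)
    tiers = ["low", "medium", "high"]
    rows = [
        {
            "species": sp,
            "skipping": sp in TETRAPOD_SKIPPING_PRESENT,
            "depth_tier": tiers[i % 3],
        }
        for i, sp in enumerate(species)
    ]
    return pd.DataFrame(rows)
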