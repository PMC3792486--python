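"""Compartment topology of the eight-compartment brain tissue model.

The model distinguishes blood, extracellular space (ECS, including the
synaptic cleft) and, for each of the three cell types (astrocyte,
glutamatergic neuron, GABAergic neuron), a cytosolic and a mitochondrial
compartment.  Vesicular neurotransmitter pools are species tags inside the
neuronal cytosols, not additional compartments.
"""

from __future__ import annotations

BLOOD = "blood"
ECS = "ECS"

CELLS = ("astrocyte", "glutamatergic", "GABAergic")

COMPARTMENTS = (
    BLOOD,
    ECS,
    "astrocyte-cytosol",
    "astrocyte-mitochondria",
    "glutamatergic-cytosol",
    "glutamatergic-mitochondria",
    "GABAergic-cytosol",
    "GABAergic-mitochondria",
)


def cytosol_of(cell: str) -> str:
    if cell not in CELLS:
        raise ValueError(f"unknown cell type: {cell!r}")
    return f"{cell}-cytosol"


def mitochondria_of(cell: str) -> str:
    if cell not in CELLS:
        raise ValueError(f"unknown cell type: {cell!r}")
    return f"{cell}-mitochondria"


def cell_of(compartment: str) -> str | None:
    """Cell type owning a compartment, or None for blood/ECS."""
    for cell in CELLS:
        if compartment in (cytosol_of(cell), mitochondria_of(cell)):
            return cell
    return None


#: Pairs of compartments a transport may connect (order = canonical
#: positive direction used throughout: into the tissue / into the cell /
#: into the mitochondria).
ADJACENT_PAIRS = frozenset(
    [(BLOOD, ECS)]
    + [(ECS, cytosol_of(c)) for c in CELLS]
    + [(cytosol_of(c), mitochondria_of(c)) for c in CELLS]
)


def are_adjacent(a: str, b: str) -> bool:
    return (a, b) in ADJACENT_PAIRS or (b, a) in ADJACENT_PAIRS
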