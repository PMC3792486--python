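"""Convenience assembly of the full brain tissue model."""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import (
    load_reaction_catalog,
    load_transport_catalog,
    packaged_boundary_document,
    packaged_model_document,
)
from .system import (
    AtomTable,
    BoundaryVector,
    StoichiometricSystem,
    assemble_system,
    boundary_vector,
)


@dataclass
class BrainModel:
    system: StoichiometricSystem
    boundary: BoundaryVector
    atoms: AtomTable
    document: dict


def build_brain_model(
    model_document: dict | None = None, boundary_document: dict | None = None
) -> BrainModel:
    """Assemble the eight-compartment model from the (packaged) documents."""
    doc = model_document if model_document is not None else packaged_model_document()
    bdoc = (
        boundary_document
        if boundary_document is not None
        else packaged_boundary_document()
    )
    reactions = load_reaction_catalog(doc)
    transports = load_transport_catalog(doc)
    system = assemble_system(reactions, transports)
    boundary = boundary_vector(
        bdoc["entries"],
        Q=bdoc["Q"],
        F=bdoc["F"],
        sigma_default=bdoc.get("sigma_default", 0.005),
        sigma_loose=bdoc.get("sigma_loose", 10.0),
    )
    atoms = AtomTable.from_document(doc)
    return BrainModel(system=system, boundary=boundary, atoms=atoms, document=doc)
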