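"""Registry of the binding assays used for polymorph profiling.

Each assay is either a direct titration of one reporter ligand or a
competition titration in which a dark competitor (L1) displaces the
reporter (L0).  The registry order is the canonical enumeration order
used for deterministic tie-breaking in the minimal-panel search.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AssayDef", "DEFAULT_ASSAYS", "CANDIDATE_ASSAYS", "PROTOCOL_ASSAYS", "ligands_of"]


@dataclass(frozen=True)
class AssayDef:
    assay_id: str
    kind: str  # direct_intensity | direct_anisotropy | competition
    reporter: str
    competitor: str | None = None

    @property
    def ligands(self) -> frozenset[str]:
        names = {self.reporter}
        if self.competitor:
            names.add(self.competitor)
        return frozenset(names)


_DEFS = [
    AssayDef("AAR-direct", "direct_intensity", "AAR"),
    AssayDef("ThT/S5H", "competition", "ThT", "S5H"),
    AssayDef("ThT/BTA", "competition", "ThT", "BTA"),
    AssayDef("ThT/OXI", "competition", "ThT", "OXI"),
    AssayDef("ThT/ThR", "competition", "ThT", "ThR"),
    AssayDef("AAR/ThT", "competition", "AAR", "ThT"),
    AssayDef("BTA-direct", "direct_anisotropy", "BTA"),
]

#: every registered assay, keyed by id, in canonical order
DEFAULT_ASSAYS: dict[str, AssayDef] = {a.assay_id: a for a in _DEFS}

#: candidate assays for the minimal-panel search (direct anisotropy is a
#: confirmatory readout of the same BTA site probed by ThT/BTA)
CANDIDATE_ASSAYS = ["AAR-direct", "ThT/S5H", "ThT/BTA", "ThT/OXI", "ThT/ThR", "AAR/ThT"]

#: the four assays of the identification protocol
PROTOCOL_ASSAYS = ["AAR-direct", "ThT/S5H", "ThT/BTA", "ThT/OXI"]


def ligands_of(assay_ids, registry: dict[str, AssayDef] | None = None) -> frozenset[str]:
    """Union of reporter and competitor ligand names over a set of assays."""
    registry = DEFAULT_ASSAYS if registry is None else registry
    out: set[str] = set()
    for aid in assay_ids:
        if aid not in registry:
            raise KeyError(f"unknown assay {aid!r}")
        out |= registry[aid].ligands
    return frozenset(out)
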