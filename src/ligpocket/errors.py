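"""Exception hierarchy shared across the package."""


class LigPocketError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(LigPocketError):
    """Malformed fixed-width PDB record; message names the offending line."""


class AtomTypingError(LigPocketError):
    """An atom could not be assigned a chemically sensible type
    (e.g. a hydrogen with no heavy atom within covalent range)."""


class TopologyError(LigPocketError):
    """Pose/model topology mismatch (atom counts or ordering differ)."""


class EnergyTableError(LigPocketError):
    """Per-pose energy table missing, malformed, or inconsistent with models."""


class SelectorError(LigPocketError):
    """An atom/residue selector resolved to no atoms."""


class DegenerateGeometryError(LigPocketError):
    """Coincident points where a finite angle or direction is required."""


class PlacementError(LigPocketError):
    """A requested planted geometry collides with existing atoms or is infeasible."""


class ActivityTableError(LigPocketError):
    """Malformed activity table row; message carries the line number."""


class ClassDefinitionError(LigPocketError):
    """Inconsistent activity-class definition (e.g. overlapping member lists)."""


class PipelineError(LigPocketError):
    """A pipeline stage failed; wraps the underlying error with stage context."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {detail}")
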