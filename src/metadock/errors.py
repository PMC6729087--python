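"""Exception hierarchy for metadock."""


class MetadockError(Exception):
    """Base class for all metadock errors."""


class PDBParseError(MetadockError):
    """A PDB record could not be parsed."""


class PDBQTParseError(MetadockError):
    """A PDBQT record or torsion-tree block is malformed."""


class EmptyStructureError(MetadockError):
    """Input text contained no atoms."""


class SelectionError(MetadockError):
    """A residue/chain/root selection matched nothing valid."""


class AmbiguityError(SelectionError):
    """A ligand selector matched more than one distinct chemical species."""


class StructureError(MetadockError):
    """The molecular graph violates a structural precondition."""


class ConsistencyError(MetadockError):
    """Two objects that must describe the same molecule disagree."""


class ConfigError(MetadockError, ValueError):
    """An engine or protocol parameter is out of range."""


class RigidLigandError(ConfigError):
    """The ligand has zero rotatable bonds; incremental scheduling does not apply."""


class PlacementError(MetadockError):
    """Random placement could not find a clash-free starting conformation."""


class EmptyPoolError(MetadockError):
    """A docking call produced no poses."""


class EngineFailureError(MetadockError):
    """An external docking binary failed; carries the tool's stderr."""

    def __init__(self, message: str, stderr: str = ""):
        super().__init__(message)
        self.stderr = stderr


class ProtocolError(MetadockError):
    """A multi-round protocol could not continue (e.g. empty selection)."""


class GenerationError(MetadockError):
    """The synthetic-complex generator exhausted its retry budget."""
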