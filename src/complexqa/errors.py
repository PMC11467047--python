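"""Exception hierarchy for complexqa.

Every error raised by the library derives from :class:`ComplexQAError` so
callers (and the CLI) can catch one base class.
"""


class ComplexQAError(Exception):
    """Base class for all complexqa errors."""


class ParseError(ComplexQAError):
    """A structure file could not be read or parsed."""


class EmptyStructureError(ParseError):
    """No chains survived parsing and normalization."""


class ClassificationError(ComplexQAError):
    """A chain mixes polymer types and cannot be assigned a molecule class."""


class UnsupportedOperationError(ComplexQAError):
    """Operation not defined for this molecule class (e.g. ligand sequence)."""


class CorrespondenceError(ComplexQAError):
    """No residue correspondence could be established for a chain pair."""


class NoNativeInterfaceError(ComplexQAError):
    """The reference chain pair has no contacts; it is not an interface."""


class InsufficientAtomsError(ComplexQAError):
    """Too few paired atoms/points for a superposition or RMSD."""


class NonIsomorphicLigandsError(ComplexQAError):
    """Model and reference ligand graphs cannot be matched."""


class EmptyPocketError(ComplexQAError):
    """No receptor residues found near the reference ligand."""


class MatchCapExceededError(ComplexQAError):
    """Ligand graph-match enumeration exceeded the configured cap."""


class IncompatibleGroupsError(ComplexQAError):
    """Model chain groups cannot be matched to any reference group."""


class MappingSpecError(ComplexQAError):
    """A user-supplied --mapping string is invalid for these structures."""
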