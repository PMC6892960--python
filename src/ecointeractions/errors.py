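"""Exception hierarchy for the ecointeractions package.

Record-level *validation* problems are reported as
:class:`~ecointeractions.datamodel.Violation` objects, not exceptions; the
classes here cover structural errors (broken vocabularies, duplicate keys,
bad mappings) where no sensible partial result exists.
"""


class EcoInteractionsError(Exception):
    """Base class for all package-specific errors."""


class VocabularyError(EcoInteractionsError):
    """A vocabulary could not be loaded, resolved or kept consistent."""


class UnknownTermError(VocabularyError, LookupError):
    """A label does not resolve in the active vocabulary."""


class DuplicateTermError(VocabularyError):
    """A label or URI would occur twice (labels compare case-insensitively)."""


class VocabularyParseError(VocabularyError):
    """A vocabulary file is malformed; the message carries a line number."""


class InverseSymmetryError(VocabularyError):
    """Term A names B as its inverse but B does not point back at A."""


class MissingInverseError(VocabularyError):
    """A term's inverse label resolves to no term in the vocabulary."""


class HierarchyCycleError(VocabularyError):
    """The parent links of an interaction-type vocabulary contain a cycle."""


class CriteriaError(EcoInteractionsError):
    """A query criteria object is internally inconsistent."""


class DuplicateUUIDError(EcoInteractionsError):
    """Two records in one dataset would share an identifier."""


class MappingError(EcoInteractionsError):
    """A column mapping is incomplete, contradictory or names absent columns."""


class TabularImportError(EcoInteractionsError):
    """Strict-mode import aborted; the message carries the offending row."""


class ExportError(EcoInteractionsError):
    """A record cannot be exported; the message names its UUID."""


class FixtureSpecError(EcoInteractionsError):
    """A synthetic-fixture specification is invalid."""
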