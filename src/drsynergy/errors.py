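"""Exception hierarchy used across the package."""


class DrsynergyError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DrsynergyError, ValueError):
    """An input value violates a documented invariant; message names the field."""


class UnknownDrugError(DrsynergyError, KeyError):
    """A drug identifier is absent from the table being queried."""


class InsufficientDataError(DrsynergyError):
    """Too few samples / cell lines / replicates to carry out the operation."""


class EmptySelectionError(DrsynergyError):
    """A metadata filter left zero treated samples; message names the filter."""


class EmptyDatasetError(DrsynergyError):
    """All candidate rows were dropped during assembly; message carries the drop ledger."""


class SchemaError(DrsynergyError):
    """Feature names / dimensions do not match what a fitted model was trained with."""


class ProtocolError(DrsynergyError):
    """An evaluation-protocol precondition is violated (e.g. mismatched fold plans)."""


class CohortParseError(DrsynergyError):
    """A cohort file on disk is missing or malformed; message names the file."""
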