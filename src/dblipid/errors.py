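"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 1, everything else under
``DBLipidError`` to exit code 2.
"""


class DBLipidError(Exception):
    """Base class for all package errors."""


class ValidationError(DBLipidError):
    """Invalid user input: bad structure, bad registry row, bad config."""


class RegistryError(ValidationError):
    """Problem loading or validating a building-block registry."""


class ReactionError(DBLipidError):
    """A virtual reaction step cannot be applied to the given reactants."""
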