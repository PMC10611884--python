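"""Exception hierarchy shared by all pdst modules."""


class PDSTError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PDSTError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(PDSTError):
    """A value violates a field invariant (wrong sign, range, or type)."""


class IntegrityError(PDSTError):
    """Cross-table referential integrity is broken (dangling or missing names)."""


class InsufficientDataError(PDSTError):
    """Too few data to run the requested derivation."""


class ConfigurationError(PDSTError):
    """A required configuration value is absent or inconsistent."""


class NameLookupError(PDSTError, KeyError):
    """An active-ingredient name is not present in the table."""

    def __init__(self, name: str, suggestions: tuple = ()):
        self.name = name
        self.suggestions = tuple(suggestions)
        hint = f"; did you mean {', '.join(self.suggestions)}?" if suggestions else ""
        super().__init__(f"unknown active ingredient {name!r}{hint}")
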