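"""Exception hierarchy shared across the package.

The CLI maps these onto stable exit codes: configuration problems exit 2,
data-validation problems exit 3, and any other stage failure exits 4.
"""


class PeriopScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(PeriopScreenError):
    """A configuration resource or user config file is invalid."""


class CodeSetError(ConfigError):
    """A code-set token could not be parsed at load time."""


class InvalidCodeError(PeriopScreenError):
    """A raw ICD-10 code string is empty or unparseable."""


class DataValidationError(PeriopScreenError):
    """Input data violated the documented schema or referential integrity.

    Carries per-row diagnostics in ``.diagnostics`` (list of strings).
    """

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics: list[str] = diagnostics or []


class StageError(PeriopScreenError):
    """A pipeline stage failed; ``.stage`` names the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
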