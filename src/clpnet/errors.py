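"""Exception hierarchy for the clpnet package.

Errors are grouped so that the command-line layer can map them onto
distinct exit codes: configuration problems, input-data validation
problems, and runtime/numerical failures.
"""


class ClpnError(Exception):
    """Base class for all clpnet errors."""


class ConfigError(ClpnError):
    """Invalid run configuration (bad paths, inconsistent options)."""


class SchemaError(ClpnError):
    """A required column or field is missing from an input table."""


class ValidationError(ClpnError):
    """Input data violates the declared value constraints."""


class ConsistencyError(ClpnError):
    """Counts or bookkeeping quantities do not add up."""


class InputError(ClpnError):
    """An operation received arguments outside its precondition."""


class ParameterError(ClpnError):
    """A model/generator parameter is invalid (e.g. non-PD matrix)."""


class DegenerateColumnError(ClpnError):
    """A symptom column has zero variance and cannot be standardized."""

    def __init__(self, node_id: str, wave: int | None = None):
        self.node_id = node_id
        self.wave = wave
        where = f" at wave {wave}" if wave is not None else ""
        super().__init__(f"zero-variance column for node {node_id!r}{where}")
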