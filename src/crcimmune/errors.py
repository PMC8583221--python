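"""Typed exceptions used across the pipeline.

Every malformed input raises one of these; nothing is silently skipped.
"""


class CrcImmuneError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(CrcImmuneError):
    """A required column or field is missing from an input table."""


class ParseError(CrcImmuneError):
    """A value in an input file could not be parsed; message carries line numbers."""


class ConfigError(CrcImmuneError):
    """A rules/thresholds/generator configuration is invalid."""


class DataError(CrcImmuneError):
    """Inputs are individually valid but jointly inconsistent
    (e.g. cells recorded in a localization without an area record)."""
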