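"""Exception hierarchy shared by all pipeline stages."""


class ShakespeareError(Exception):
    """Base class for all package errors."""


class ConfigError(ShakespeareError, ValueError):
    """Invalid configuration value (probability out of range, empty vocabulary...)."""


class SchemaError(ShakespeareError, ValueError):
    """Input table does not match the expected schema, or rows are malformed."""


class PipelineError(ShakespeareError, RuntimeError):
    """A pipeline stage cannot run, e.g. a required upstream artifact is missing."""
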