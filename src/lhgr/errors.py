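"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


class DegenerateIntervalError(ValueError):
    """An interval contains no usable (non-N) bases for the requested statistic."""


class ConfigError(ValueError):
    """A run configuration is inconsistent or references missing inputs."""


class DataError(ValueError):
    """Input data is structurally valid but unusable for the requested stage."""
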