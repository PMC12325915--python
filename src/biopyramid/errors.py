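"""Exception types shared across the pipeline."""


class BiopyramidError(Exception):
    """Base class for all package-specific errors."""


class InputError(BiopyramidError, ValueError):
    """Malformed or inconsistent input data (bad timestamps, unknown stations...)."""


class ConfigError(BiopyramidError, ValueError):
    """Invalid configuration: missing traits, bad simulation parameters, improper priors."""


class ModelError(BiopyramidError, ValueError):
    """Model precondition violated (e.g. truncation bound below an observed count)."""
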