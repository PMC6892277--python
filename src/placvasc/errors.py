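"""Exception hierarchy shared across the pipeline."""


class PlacvascError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(PlacvascError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(PlacvascError):
    """Malformed or missing input data (CLI exit code 3)."""


class ThresholdDetectionError(DataError):
    """Automatic histogram peak detection failed; manual thresholds required."""
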