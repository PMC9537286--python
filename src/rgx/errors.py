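"""Exception types shared across the pipeline."""


class RgxError(Exception):
    """Base class for all package errors."""


class SizingError(RgxError):
    """Degenerate geometry request (non-positive size or spacing, sigma below grid scale)."""


class DegenerateRoiError(RgxError):
    """A region of interest became empty after resampling or intensity re-segmentation."""


class ModelError(RgxError):
    """Model fitting could not proceed (no events, separation, non-convergence...)."""


class ConfigError(RgxError):
    """Invalid configuration or unknown keys."""
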