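"""Exception hierarchy shared across the toolkit."""


class RiscreenError(Exception):
    """Base class for all riscreen errors."""


class LadderError(RiscreenError):
    """An alkane ladder violates its structural invariants."""


class RIRangeError(RiscreenError):
    """A retention time or index falls outside the calibrated span."""


class FitError(RiscreenError):
    """A least-squares reconstruction could not be carried out."""


class TraceError(RiscreenError):
    """A chromatogram trace is malformed or too short to process."""


class NoiseEstimationError(RiscreenError):
    """Too few baseline points to estimate noise."""


class PanelError(RiscreenError):
    """A pesticide panel file violates its schema."""


class ScheduleError(RiscreenError):
    """No valid MRM time segmentation exists for the given limits."""


class ConfigError(RiscreenError):
    """A pipeline configuration is inconsistent or incomplete."""
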