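"""Exception hierarchy shared across the package."""


class DropscreenError(ValueError):
    """Base class for all package-specific errors."""


class LibraryError(DropscreenError):
    """Invalid sgRNA library or domain-map input."""


class SimulationError(DropscreenError):
    """Invalid simulator configuration or arguments."""


class CountingError(DropscreenError):
    """Problems while quantifying reads or assembling count matrices."""


class ScoringError(DropscreenError):
    """Problems in the dropout-scoring stages."""
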