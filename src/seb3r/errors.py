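"""Exception hierarchy shared across the pipeline."""


class Seb3rError(Exception):
    """Base class for all package errors."""


class FormatError(Seb3rError):
    """A tracking or intermediate CSV is malformed (empty, ragged, wrong columns)."""


class MissingHotspotError(FormatError):
    """A required body part is absent from a tracking file header."""

    def __init__(self, hotspot: str, path=None):
        self.hotspot = hotspot
        self.path = path
        loc = f" in {path}" if path else ""
        super().__init__(f"required hotspot {hotspot!r} not found{loc}")


class LayoutError(Seb3rError):
    """The mother-folder layout violates the expected cohort conventions."""
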