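"""Stage-tagged exception hierarchy.

Every pipeline failure carries the name of the stage that raised it so that
CLI error messages and summary files can point at the failing step.
"""

from __future__ import annotations


class MicrospotError(Exception):
    """Base class; ``stage`` names the pipeline step that failed."""

    stage: str = "general"

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        if stage is not None:
            self.stage = stage

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"[{self.stage}] {super().__str__()}"


class InputError(MicrospotError):
    """Missing or unreadable input file."""

    stage = "io"


class FormatError(MicrospotError):
    """Decodable-but-unsupported image or layout content."""

    stage = "io"


class ConfigError(MicrospotError):
    """Invalid run configuration value."""

    stage = "config"


class LayoutError(MicrospotError):
    """Array layout violates an invariant."""

    stage = "layout"


class DetectionError(MicrospotError):
    """Blob detection or anchor matching failed."""

    stage = "detection"


class GeometryError(MicrospotError):
    """Transform estimation or image warping failed."""

    stage = "geometry"


class QuantError(MicrospotError):
    """ROI measurement or aggregation failed."""

    stage = "quantification"


class QCError(MicrospotError):
    """Chip-level quality control failed (e.g. positive control not above background)."""

    stage = "qc"
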