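"""Exception hierarchy for the pipeline.

All errors raised by organoidq derive from :class:`OrganoidQError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class OrganoidQError(Exception):
    """Base class for all organoidq errors."""


class InputError(OrganoidQError):
    """Invalid user-supplied value (bad counts, empty rasters, bad records)."""


class FormatError(OrganoidQError):
    """Malformed file or inconsistent raster geometry."""


class ConsistencyError(OrganoidQError):
    """Cross-artifact mismatch (e.g. object missing from a blinding manifest)."""


class StateError(OrganoidQError):
    """Operation requires state that is absent (e.g. an untrained model)."""


class ComputationError(OrganoidQError):
    """A quantity is undefined for the given data (e.g. zero control mean)."""


class PlacementError(OrganoidQError):
    """Synthetic scene objects could not be placed within the attempt budget."""
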