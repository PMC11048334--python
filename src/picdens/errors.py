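"""Exception hierarchy for the picdens pipeline."""


class PicdensError(Exception):
    """Base class for all picdens errors."""


class ParameterError(PicdensError, ValueError):
    """A configuration parameter is outside its valid range."""


class InputError(PicdensError, ValueError):
    """An input image, interval or series violates a precondition."""


class DegenerateHistogramError(InputError):
    """A gray-level histogram with fewer than two populated levels:
    no wall/void split exists."""


class DataError(PicdensError, ValueError):
    """Inconsistent ring annotations or series (overlaps, duplicates,
    unmatched records)."""


class InsufficientOverlapError(PicdensError, ValueError):
    """Two annual series share fewer common years than the minimum
    required for a correlation."""


class GenerationError(PicdensError, ValueError):
    """A synthetic-wood porosity target is not renderable (vessels of the
    requested size cannot be packed densely enough)."""
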