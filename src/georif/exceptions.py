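"""Exception hierarchy for georif."""


class GeorifError(Exception):
    """Base class for all georif errors."""


class FormatError(GeorifError, ValueError):
    """Malformed input file: bad counts, duplicate identifiers, wrong layout."""


class DesignError(GeorifError, ValueError):
    """Invalid experimental design: wrong number of conditions, too few samples."""


class PipelineError(GeorifError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
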