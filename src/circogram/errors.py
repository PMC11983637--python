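"""Exception hierarchy.

Every error raised by circogram derives from :class:`CircogramError` so
callers (and the CLI) can separate composition-time failures from
render-time failures.
"""


class CircogramError(Exception):
    """Base class for all circogram errors."""


# --- composition / grammar ------------------------------------------------

class IllegalComposition(CircogramError):
    """A component was added to a container the algebra does not allow."""


class UnknownInitMode(CircogramError):
    """initMode is not one of the four documented values."""


class MissingInitArgument(CircogramError):
    """A required initialization argument for the chosen mode is absent."""


class UnknownInitArgument(CircogramError):
    """An initialization argument is not recognised for the chosen mode."""


class InvalidParameterValue(CircogramError):
    """A global-parameter key is unknown or its value is out of range."""


# --- layout ---------------------------------------------------------------

class DegenerateRange(CircogramError):
    """A sector xlim has max <= min."""


class GapOverflow(CircogramError):
    """Sector gaps sum to 360 degrees or more."""


class RadiusExhausted(CircogramError):
    """Cumulative track heights and margins exceed the unit radius."""


# --- geoms ----------------------------------------------------------------

class UnknownGeomKind(CircogramError):
    """Geometry kind is not in the registry."""


class UnknownAesthetic(CircogramError):
    """An aesthetic key is not valid for the geometry kind."""


class MalformedTrackData(CircogramError):
    """Track data table lacks required columns or is ragged."""


class MalformedGeomData(CircogramError):
    """Concrete coordinate vectors disagree in length or type."""


class NoDefaultAvailable(CircogramError):
    """A coordinate was left absent but the owning track has no data to
    default from for that sector."""


class CallableResultInvalid(CircogramError):
    """A coordinate callable returned a value of the wrong length/type."""


# --- genomic --------------------------------------------------------------

class ParseError(CircogramError):
    """A text record could not be parsed; message carries the line number."""


class InvalidStain(CircogramError):
    """Cytoband stain code outside the Giemsa vocabulary."""


class CoordinateError(CircogramError):
    """Genomic coordinates violate the 0-based half-open convention."""


class UnknownChromosome(CircogramError):
    """A zoom subset or link endpoint names a chromosome not in the genome."""


class RowCountMismatch(CircogramError):
    """Paired link region tables differ in row count."""


# --- renderer -------------------------------------------------------------

class UnknownSector(CircogramError):
    """A link endpoint references a sector absent from the layout."""


class EmptyInterval(CircogramError):
    """A ribbon link endpoint interval has zero angular width."""


class DocumentError(CircogramError):
    """A declarative plot document failed schema validation."""
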