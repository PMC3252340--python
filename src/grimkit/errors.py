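"""Exception hierarchy for grimkit.

Every error raised by the library derives from :class:`GrimError`, so callers
(and the CLI) can catch one type.  Subclasses are fine-grained because the
simulation distinguishes many failure modes a bench scientist would also
distinguish: bad alphabet, unparseable file, impossible assembly, wrong site
topology, and so on.
"""


class GrimError(Exception):
    """Base class for all grimkit errors."""


class AlphabetError(GrimError):
    """Sequence contains characters outside the accepted nucleotide alphabet."""


class ParseError(GrimError):
    """A sequence file could not be parsed; the message names the file/record."""


class ParameterError(GrimError):
    """A numeric or flag parameter is out of its valid range."""


class ConfigurationError(GrimError):
    """A required packaged resource constant is missing or inconsistent."""


class InputTooShortError(GrimError):
    """The design query is shorter than one target-site window."""


class AssemblyError(GrimError):
    """Overlap-extension assembly found no valid oligo chain."""


class AmbiguousAssemblyError(AssemblyError):
    """More than one exact overlap placement satisfies a junction."""


class AnnotationError(GrimError):
    """A donor segment could not be recognized at its expected offset."""


class SiteTopologyError(GrimError):
    """A recombination substrate lacks (or duplicates) a required site."""


class PartnerSpecificityError(SiteTopologyError):
    """Sites were offered to a recombinase pairing they cannot undergo."""


class InsufficientSitesError(SiteTopologyError):
    """Fewer than two sites available for an intramolecular Cre/Flp event."""


class MultiSiteError(SiteTopologyError):
    """More than two sites present and no explicit pair was named."""


class MissingFeatureError(GrimError):
    """A record lacks a feature the operation requires (e.g. a promoter)."""


class OrientationError(GrimError):
    """A feature or site is in an orientation the operation does not support."""


class ConstraintError(GrimError):
    """Fixture geometry constraints are unsatisfiable; message shows arithmetic."""
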