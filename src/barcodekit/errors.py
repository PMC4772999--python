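"""Exception hierarchy shared across the package."""


class BarcodekitError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(BarcodekitError):
    """Sequences do not form a valid alignment (e.g. unequal lengths)."""


class MetadataError(BarcodekitError):
    """Metadata table is missing, malformed, or inconsistent with the FASTA."""


class DuplicateIdError(BarcodekitError):
    """The same sequence id occurs more than once."""


class ScenarioError(BarcodekitError):
    """A synthetic scenario could not realise its declared property."""


class ConfigurationError(BarcodekitError):
    """Pipeline configuration is invalid or incomplete."""
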