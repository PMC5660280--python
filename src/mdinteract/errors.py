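"""Exception hierarchy shared across the package."""


class MdinteractError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MdinteractError):
    """Unparseable or unwritable file content (carries context such as a line number)."""


class TopologyError(MdinteractError):
    """Inconsistent atom content between trajectory models/systems."""


class SelectionError(MdinteractError):
    """Malformed selection expression or a selection with the wrong cardinality."""


class GeometryError(MdinteractError):
    """Degenerate geometric input (zero-length arm, non-planar ring, ...)."""


class DetectionError(MdinteractError):
    """A profile feature (e.g. an RDF first minimum) could not be located."""


class ConfigurationError(MdinteractError):
    """Invalid analysis configuration (missing radius, unknown parameter row, ...)."""
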