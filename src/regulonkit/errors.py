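"""Exception hierarchy shared across the package."""


class RegulonKitError(Exception):
    """Base class for all regulonkit errors."""


class FormatError(RegulonKitError, ValueError):
    """Malformed input file (duplicate locus_tag, unknown strand, ...)."""


class CoordinateError(RegulonKitError, ValueError):
    """Feature coordinates inconsistent with the sequence they annotate."""


class ParameterError(RegulonKitError, ValueError):
    """Invalid parameter value (negative gap, odd motif length, ...)."""


class InputError(RegulonKitError, ValueError):
    """Invalid data passed to an operation (empty sequence, bad residue, ...)."""


class ConfigError(RegulonKitError, ValueError):
    """Inconsistent simulator configuration."""


class PlacementError(RegulonKitError, ValueError):
    """A motif instance cannot be implanted where requested."""


class DiscoveryError(RegulonKitError, RuntimeError):
    """Motif discovery cannot run on the given training regions."""


class ConsistencyError(RegulonKitError, ValueError):
    """Cross-references between objects do not line up."""
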