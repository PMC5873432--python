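"""Exception types shared across the package."""


class CovnetError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(CovnetError, ValueError):
    """Subject/region identifiers do not line up across input tables."""


class ParseError(CovnetError, ValueError):
    """A cell of an on-disk table could not be interpreted."""


class InvariantError(CovnetError, ValueError):
    """A data-structure invariant (symmetry, domain, uniqueness) is violated."""


class DegenerateDataError(CovnetError, ValueError):
    """The data are degenerate for the requested computation
    (zero-variance region, all-tied correlations, empty inputs...)."""


class ConfigError(CovnetError, ValueError):
    """An invalid configuration value or combination."""
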