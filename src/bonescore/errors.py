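"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`BoneScoreError`
so callers can catch one base class at pipeline boundaries.
"""


class BoneScoreError(Exception):
    """Base class for all bonescore errors."""


class ConfigurationError(BoneScoreError, ValueError):
    """Invalid simulation or run configuration."""


class InputError(BoneScoreError, ValueError):
    """Malformed or empty input data."""


class ContractError(BoneScoreError, ValueError):
    """A call violated an interface contract (e.g. variable-order mismatch)."""


class DegenerateStratumError(BoneScoreError, ValueError):
    """A standardization stratum has n < 2 or zero spread in some variable."""


class DegenerateVariableError(BoneScoreError, ValueError):
    """A variable is constant where variation is required (PCA input)."""


class InestimableDesignError(BoneScoreError, ValueError):
    """A factorial term cannot be estimated (empty cell, aliased design)."""


class TopologyError(BoneScoreError, ValueError):
    """A cross-section mask violates the expected cortex/marrow topology."""


class UnusableCurveError(BoneScoreError, ValueError):
    """A force-displacement trace cannot be analyzed (e.g. never reaches preload)."""
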