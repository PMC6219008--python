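"""Exception hierarchy shared across the package."""


class RankscoreError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RankscoreError):
    """Raised when an input file cannot be parsed."""


class ValidationError(RankscoreError, ValueError):
    """Raised when inputs violate a documented invariant."""


class ScoringError(RankscoreError):
    """Raised when a signature cannot be scored against a sample."""


class DegenerateBoundsError(ScoringError):
    """Raised when the theoretical score bounds collapse (S_max == S_min)."""
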