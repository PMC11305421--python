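"""Package-wide exception types.

Every error a caller is expected to catch is a named subclass of
:class:`Abca4FuncError`; nothing in the pipeline raises a bare ``ValueError``
for a domain-level failure.
"""


class Abca4FuncError(Exception):
    """Base class for all errors raised by abca4func."""


class MissingWildTypeError(Abca4FuncError):
    """An experiment contains variant measurements but no wild-type reference."""


class ZeroWildTypeSignalError(Abca4FuncError):
    """The wild-type reference signal is zero or negative and cannot normalize."""


class ZeroStimulationWindowError(Abca4FuncError):
    """WT stimulated minus basal activity is zero; S is undefined."""


class NoCommonExperimentsError(Abca4FuncError):
    """Variant and wild type share no experiments; per-replicate F undefined."""


class HgvsParseError(Abca4FuncError):
    """A cDNA or protein change string is outside the supported HGVS subset."""

    def __init__(self, token: str, message: str = "") -> None:
        self.token = token
        super().__init__(message or f"cannot parse HGVS token {token!r}")


class EvidenceConflictError(Abca4FuncError):
    """Two pass-through entries assert different strengths for the same code."""


class SimulationSpecError(Abca4FuncError):
    """A simulation specification is invalid (negative cv, n < 1, ...)."""


class ConfigError(Abca4FuncError):
    """A run configuration file is malformed or contains unknown keys."""
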