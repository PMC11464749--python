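"""Exception hierarchy shared across the pipeline stages."""


class QSPRError(Exception):
    """Base class for all package errors."""


class ConfigError(QSPRError):
    """Malformed or unreadable configuration document."""


class ValidationError(QSPRError):
    """One or more declared invariants violated.

    ``violations`` lists every violated constraint, not just the first.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ContractError(QSPRError):
    """A caller broke an operation precondition (e.g. unfitted transform)."""


class CapabilityError(QSPRError):
    """The requested operation is not supported for this model family."""


class ArtifactError(QSPRError):
    """Serialized model artifact is unreadable or version-incompatible."""
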