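"""Exception types shared across the package."""


class PhenoruleError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhenoruleError):
    """Invalid configuration: bad rule pattern, malformed column mapping, ..."""


class DataError(PhenoruleError):
    """Input data violates a contract (stray ids, impossible counts, ...)."""


class UnresolvedCaseError(PhenoruleError):
    """Two primary reviewers disagree and no third verdict is available."""

    def __init__(self, patient_id: str):
        self.patient_id = patient_id
        super().__init__(
            f"reviewers disagree for patient {patient_id!r} and no third verdict "
            "is available to arbitrate"
        )
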