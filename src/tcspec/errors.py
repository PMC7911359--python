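"""Exception hierarchy for tcspec."""


class TcspecError(Exception):
    """Base class for all tcspec errors."""


class AlignmentError(TcspecError):
    """Malformed or inconsistent alignment input (ragged rows, duplicate ids)."""


class PairingError(TcspecError):
    """A pair table references an id that does not resolve in its alignment."""


class EncodingError(TcspecError):
    """A sequence cannot be encoded/decoded under the given alphabet."""


class StructureError(TcspecError):
    """Malformed structure file or unusable chain."""


class InferenceError(TcspecError):
    """Numerical failure during model inference (e.g. singular correlation matrix)."""


class ScoringError(TcspecError):
    """Incompatible model/mask/sequence combination during scoring."""


class MutationError(TcspecError):
    """Invalid mutation specification."""


class ConfigError(TcspecError):
    """Invalid pipeline configuration."""
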