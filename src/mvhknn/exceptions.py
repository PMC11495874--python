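"""Exception and warning types used across the package."""


class MvhknnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MvhknnError, ValueError):
    """An invalid hyperparameter or an impossible request (e.g. K larger
    than the class it draws neighbours from)."""


class DegenerateInputError(MvhknnError, ValueError):
    """Input on which the requested quantity is undefined (zero-norm vector
    under cosine similarity, constant vector under Pearson correlation)."""


class ContractViolationError(MvhknnError, ValueError):
    """A caller broke an in-memory contract (shape mismatch, asymmetric or
    negative adjacency, ...)."""


class DataError(MvhknnError, ValueError):
    """Malformed external input: feature tables, FASTA files, config files."""


class SingularSystemWarning(UserWarning):
    """A linear system was singular; a least-norm solution was returned."""


class MetricWarning(UserWarning):
    """A metric hit a degenerate case (e.g. MCC with a zero marginal)."""
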