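"""Exception hierarchy."""


class MitoclockError(Exception):
    """Base class for all package errors."""


class FormatError(MitoclockError):
    """Malformed external file (FASTA, TSV, Newick, ...)."""


class ValidationError(MitoclockError):
    """A domain invariant is violated (negative age, bad simplex, ...)."""


class StructureError(MitoclockError):
    """A tree violates structural requirements (polytomy, negative branch)."""


class SimulationError(MitoclockError):
    """A stochastic simulation cannot proceed (e.g. lineages cannot coalesce)."""


class NumericalError(MitoclockError):
    """Non-finite intermediate in a numerical routine."""
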