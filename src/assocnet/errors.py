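"""Exception hierarchy.

Everything the toolkit raises deliberately derives from :class:`AssocNetError`,
so callers (and the CLI) can distinguish domain errors (exit code 1) from
programming errors and usage errors (exit code 2).
"""


class AssocNetError(Exception):
    """Base class for all domain errors raised by assocnet."""


class InvalidArgumentError(AssocNetError, ValueError):
    """An argument violates a documented precondition."""


class AmbiguousAliasError(AssocNetError):
    """An alias resolves to more than one protein for a species."""

    def __init__(self, alias: str, taxid: int, candidates: list[str]):
        self.alias = alias
        self.taxid = taxid
        self.candidates = sorted(candidates)
        super().__init__(
            f"alias {alias!r} is ambiguous for taxid {taxid}: "
            f"candidates {', '.join(self.candidates)}"
        )


class EmptyQueryError(AssocNetError):
    """No query identifier could be resolved."""


class EmptyResultError(AssocNetError):
    """A query has no result (e.g. no cross-species edge at the cutoff)."""


class NotFoundError(AssocNetError):
    """A named entity is unknown."""


class InvalidSelectionError(AssocNetError):
    """A node selection refers to ids absent from the network."""


class InvalidBackgroundError(AssocNetError):
    """Enrichment query and background are disjoint."""


class NoGroupsError(AssocNetError):
    """The grouping attribute is absent from every node."""


class DegenerateSequenceError(AssocNetError):
    """A sequence has a non-positive self-alignment score."""


class MissingLineageError(AssocNetError):
    """A taxid has no lineage entry in the taxonomy table."""


class ConvergenceError(AssocNetError):
    """Markov clustering failed to converge within the iteration budget."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"MCL did not converge after {iterations} iterations "
            f"(residual {residual:.3g})"
        )


class WorldSpecError(AssocNetError):
    """A synthetic-world specification is internally inconsistent."""


class ParseError(AssocNetError):
    """A file could not be parsed; message carries line/element context."""
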