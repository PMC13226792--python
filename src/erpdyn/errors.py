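"""Exception hierarchy used across the pipeline."""


class ErpdynError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ErpdynError, ValueError):
    """An argument violates an operation's precondition."""


class EmptyResultError(ErpdynError, ValueError):
    """An operation would produce an empty result (e.g. all trials rejected)."""


class UndefinedValueError(ErpdynError, ValueError):
    """A requested quantity is undefined for the given data (e.g. unvisited state)."""


class FormatError(ErpdynError, ValueError):
    """An on-disk container is malformed or inconsistent with its sidecar."""
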