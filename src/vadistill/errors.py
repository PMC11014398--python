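"""Shared exception types."""


class InvalidArgumentError(ValueError):
    """A precondition on an operation's arguments was violated."""


class InvalidStateError(RuntimeError):
    """An operation was applied to an object in the wrong state."""
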