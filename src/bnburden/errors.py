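"""Exception hierarchy.

Every error the package raises deliberately derives from :class:`BNBurdenError`
so callers (and the CLI) can distinguish data/model problems from bugs.
"""

from __future__ import annotations


class BNBurdenError(Exception):
    """Base class for all package errors."""


class InputError(BNBurdenError, ValueError):
    """Invalid user input: unknown node/state, malformed evidence, bad config."""


class NetworkInvalidError(BNBurdenError):
    """An operation refused to run on a network that fails validation."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"network failed validation:\n{report}")


class InconsistentEvidenceError(BNBurdenError):
    """The evidence program has probability zero under the model."""


class ParseError(BNBurdenError):
    """A file could not be parsed; message carries line/element context."""


class SchemaMismatchError(InputError):
    """A trial template requires nodes/states the network does not provide."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "network does not match the template schema; missing: "
            + ", ".join(self.missing)
        )


class ElicitationWarning(UserWarning):
    """Non-fatal elicitation issue (e.g. infeasible CI fell back to a PERT fit)."""
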