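"""Exception hierarchy.

Every error the library raises on bad user input derives from :class:`SpinError`,
so callers (and the CLI) can distinguish schema/contract violations from bugs.
"""


class SpinError(ValueError):
    """Base class for all input-contract violations."""


class GmtParseError(SpinError):
    """A GMT line could not be parsed."""


class MaskError(SpinError):
    """No usable pathway mask can be built from the inputs."""


class SchemaError(SpinError):
    """Dataset/clinical table does not match the requested task or model."""
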