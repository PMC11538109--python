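"""Exception types shared across the package."""


class MpmToolsError(Exception):
    """Base class for all package errors."""


class EmptyInputError(MpmToolsError):
    """An operation received no data (empty file list, empty stack, empty graph)."""


class ShapeMismatchError(MpmToolsError):
    """Input images do not share a common shape."""


class ConfigurationError(MpmToolsError):
    """An invalid option or parameter value was supplied."""


class DegenerateInputError(MpmToolsError):
    """Input carries no usable signal (e.g. constant image passed to a mixture fit)."""


class LabelError(MpmToolsError):
    """Training labels are unusable (single class, non-binary mask)."""


class EmptyWellError(MpmToolsError):
    """A well boundary with zero interior area was supplied."""


class FixtureSpecError(MpmToolsError):
    """A synthetic-fixture specification is internally inconsistent."""
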