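"""Exception hierarchy shared across the toolkit."""


class HistostressError(Exception):
    """Base class for all package-specific errors."""


class PatchFormatError(HistostressError):
    """A patch file is missing, not 8-bit, or not 3-channel RGB."""


class InsufficientTissueError(HistostressError):
    """Too few non-background pixels to estimate stain vectors."""


class DegenerateStainError(HistostressError):
    """The optical-density cloud is effectively one-dimensional (single stain)."""


class ClassifierContractError(HistostressError):
    """A plug-in classifier returned malformed class probabilities."""
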