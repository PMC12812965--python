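"""Exception types raised across the package."""


class MDLCAError(Exception):
    """Base class for package-specific errors."""


class DimensionError(MDLCAError, ValueError):
    """Array shapes are incompatible for the requested operation."""


class DegenerateMaskError(MDLCAError, ValueError):
    """Brain mask contains too few foreground voxels to be usable."""


class ConstantVolumeError(MDLCAError, ValueError):
    """Within-mask intensities have zero spread; z-scoring is undefined."""


class EmptyPanelError(MDLCAError, ValueError):
    """Quality control removed every gene from the expression panel."""


class EmptyGraphError(MDLCAError, ValueError):
    """A gene graph with no nodes was passed where one is required."""


class IsolatedNodeError(MDLCAError, ValueError):
    """A node has an empty neighborhood and self-loops are disabled."""


class StratificationError(MDLCAError, ValueError):
    """A class has too few patients for a stratified split."""


class CheckpointError(MDLCAError, IOError):
    """A model checkpoint file is missing, corrupt, or incompatible."""
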