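"""Exception types shared across the package."""


class NeuroskelError(Exception):
    """Base class for all package-specific errors."""


class EmptyObjectError(NeuroskelError):
    """An operation that needs foreground voxels received none."""


class FormatError(NeuroskelError):
    """A file (SWC text, binary SWC, score table, synapse CSV) is malformed."""


class TooSmallError(NeuroskelError):
    """An input has too few points/nodes for the requested operation."""


class DegenerateNeuronError(NeuroskelError):
    """A neuron's self-similarity score is zero; it cannot be normalized."""


class UndefinedFeatureError(NeuroskelError):
    """A morphometric is undefined for this input (degenerate geometry)."""
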