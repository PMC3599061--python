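"""Exception hierarchy for the identifier toolkit."""


class MinichiError(Exception):
    """Base class for all toolkit errors."""


class MolfileParseError(MinichiError):
    """Raised on a syntactically invalid connection table.

    ``line`` is the 1-based line number within the Molfile record.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SizeLimitError(MinichiError):
    """Structure exceeds the 1000-atom limit."""


class ElementError(MinichiError):
    """Unknown or unsupported element symbol."""


class UnsupportedFeatureError(MinichiError):
    """Input uses a feature outside this tool's scope (V3000, aromatic
    bond type, query features, exotic explicit hydrogens, ...)."""


class ValenceError(MinichiError):
    """Explicit bonds exceed every allowed valence of an atom."""


class StereoConflictError(MinichiError):
    """Contradictory wedge flags around one stereocenter."""


class GeometryError(MinichiError):
    """Degenerate 2D geometry prevents stereo perception."""


class IdentifierParseError(MinichiError):
    """Malformed identifier string; ``layer`` names the offending layer."""

    def __init__(self, message: str, layer: str | None = None):
        self.layer = layer
        if layer is not None:
            message = f"layer '{layer}': {message}"
        super().__init__(message)


class ReconstructionError(MinichiError):
    """Valence filling could not complete a parsed structure.

    ``partial`` carries the graph as far as it was rebuilt.
    """

    def __init__(self, message: str, partial=None):
        self.partial = partial
        super().__init__(message)


class CanonicalizationLimitError(MinichiError):
    """Branch-and-bound node-expansion cap exceeded."""
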