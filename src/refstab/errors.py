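"""Exception hierarchy shared across the package."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class FormatError(RefstabError):
    """A file could not be parsed into the expected table layout."""


class ValidationError(RefstabError):
    """Parsed data violates a domain invariant (range, uniqueness, alignment)."""


class ParameterError(RefstabError):
    """An algorithm parameter is outside its admissible range."""


class AnalysisError(RefstabError):
    """Input is structurally valid but insufficient for the requested analysis."""
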