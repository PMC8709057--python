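"""Exception hierarchy.

Argument errors (bad parameter values) raise plain :class:`ValueError`;
:class:`DataError` marks inputs that are structurally valid but whose
*content* violates a precondition (e.g. a zero-variance trial, a trial too
short for the analysis window, a degenerate attack template).
"""


class DataError(ValueError):
    """Input data violates a content precondition of an operation."""
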