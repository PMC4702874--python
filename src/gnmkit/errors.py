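"""Exception hierarchy for the gnmkit pipeline.

Each pipeline stage raises a distinct subclass so that callers (and the
command-line driver) can map failures to exit codes without string matching.
"""


class GnmkitError(Exception):
    """Base class for all gnmkit errors."""


class ParseError(GnmkitError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(ParseError):
    """The file contains no ATOM/HETATM coordinate records."""


class AssemblyError(GnmkitError):
    """A biological-assembly operator could not be applied."""


class EmptyNetworkError(GnmkitError):
    """No eligible network nodes could be selected from the structure."""


class DisconnectedNetworkError(GnmkitError):
    """The spring network has more than one connected component."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


class SpectralConsistencyError(GnmkitError):
    """Numerical zero-mode count disagrees with the graph component count."""


class UndefinedCorrelationError(GnmkitError):
    """A correlation is undefined (zero variance / zero subset fluctuation)."""

    def __init__(self, message, nodes=None):
        super().__init__(message)
        self.nodes = nodes or []


class ContractError(GnmkitError):
    """An argument violates an operation's documented contract."""


class MissingDataError(GnmkitError):
    """Required experimental data (e.g. B-factors) are absent."""
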