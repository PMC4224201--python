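"""Exception hierarchy for gfdnet.

Input problems (bad files, unknown identifiers) and method preconditions
(no scorable edges, search space over the cap) get distinct types so the
CLI can map them to exit codes.
"""


class GfdnetError(Exception):
    """Base class for all gfdnet errors."""


class FormatError(GfdnetError):
    """A file could not be parsed; the message names file and line."""

    def __init__(self, path, line_no, message):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{self.path}:{line_no}: {message}")


class EmptyOntologyError(GfdnetError):
    """The requested namespace contains no terms."""


class UnknownTermError(GfdnetError, KeyError):
    """A GO accession is not present in the loaded DAG."""

    def __init__(self, accession):
        self.accession = accession
        super().__init__(f"unknown GO term: {accession}")

    def __str__(self):  # KeyError quotes its args; keep the plain message
        return self.args[0]


class EmptyNetworkError(GfdnetError):
    """The network file contains no nodes."""


class NoScorableEdgesError(GfdnetError):
    """After removing unannotated genes no edge remains to score."""


class SearchSpaceTooLargeError(GfdnetError):
    """The product of candidate-set sizes exceeds the configured cap."""

    def __init__(self, size, cap):
        self.size = size
        self.cap = cap
        super().__init__(
            f"search space of {size} combinations exceeds cap {cap}; "
            "use branch-and-bound or greedy mode"
        )


class IncompleteAssignmentError(GfdnetError):
    """An edge endpoint has no selected term in the assignment."""
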