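"""Exception hierarchy.

Each typed error carries an ``exit_code`` so the command-line layer can map
failures onto stable process exit statuses (2 validation, 3 incompatible
dimensions, 4 not-a-tree/forest).
"""


class BrauerPhyloError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class ValidationError(BrauerPhyloError):
    """Malformed input: bad partition, bad Newick, bad labels."""

    exit_code = 2


class DimensionMismatchError(BrauerPhyloError):
    """Diagram composition attempted between incompatible shapes.

    Composition of an (n, m) diagram with an (m', k) diagram is defined only
    when m == m' (the partial-monoid constraint).
    """

    exit_code = 3


class NotAForestError(BrauerPhyloError):
    """A diagram or product fails the forest count condition m = l(pi) - tau."""

    exit_code = 4

    def __init__(self, message, diagram=None, classification=None):
        super().__init__(message)
        self.diagram = diagram
        self.classification = classification


class NotATreeError(NotAForestError):
    """A diagram or product is not the image of a single rooted tree."""

    exit_code = 4


class MalformedPartitionError(ValidationError):
    """The forest-building recursion found no eligible block.

    For a genuine set partition of {1..t} this cannot happen (at every step
    at least one unprocessed non-trivial block lies inside the current label
    range), so reaching this error indicates a corrupted input object.
    """
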