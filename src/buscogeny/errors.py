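"""Exception hierarchy.

Everything the library raises deliberately derives from ``BuscogenyError`` so
callers (and the CLI) can separate expected failures from bugs.
"""


class BuscogenyError(Exception):
    """Base class for all deliberate pipeline errors."""


class ValidationError(BuscogenyError):
    """Bad argument values or violated preconditions."""


class LineageDatasetError(BuscogenyError):
    """The lineage dataset directory is missing or malformed."""


class HarvestError(BuscogenyError):
    """A BUSCO result file could not be harvested."""


class AlignmentError(BuscogenyError):
    """Rows that should form an alignment do not."""


class ParseError(BuscogenyError):
    """A structured text file (newick, importation status) failed to parse."""


class ExternalToolError(BuscogenyError):
    """An external tool invocation returned a nonzero exit status."""
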