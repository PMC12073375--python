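"""Exception hierarchy shared by all fibermesh modules.

Each class carries the process exit code the command-line layer maps it to.
"""


class FibermeshError(Exception):
    """Base class for all errors raised by fibermesh."""

    exit_code = 1


class ValidationError(FibermeshError):
    """Invalid user input: parameters, spec fields, malformed tables."""

    exit_code = 2


class ImageIOError(FibermeshError):
    """A file could not be read or written."""

    exit_code = 3


class ComputationError(FibermeshError):
    """A stage failed on otherwise valid input (e.g. no threshold exists)."""

    exit_code = 4
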