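"""Exception hierarchy.

All imflow-specific failures derive from :class:`ImflowError` so callers can
catch the library's errors without masking programming mistakes.
"""


class ImflowError(Exception):
    """Base class for all imflow errors."""


class ConfigurationError(ImflowError):
    """An invalid option value (unknown store method, bad choice, ...)."""


class BoundsError(ImflowError):
    """A coordinate falls outside the extent it must fit in."""


class RelationshipError(ImflowError):
    """Illegal object relationship (self-parenting, ancestry cycle, ...)."""


class WorkspaceError(ImflowError):
    """Name clash or missing item in a workspace."""


class ValidationError(ImflowError):
    """A module received structurally invalid inputs."""


class WorkflowParseError(ImflowError):
    """A workflow document could not be read."""


class GenerationError(ImflowError):
    """A synthetic fixture could not be generated under its constraints."""
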