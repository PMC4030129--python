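"""Exception hierarchy.

Everything raised deliberately by the package derives from :class:`EnmdynError`
so callers can catch one type at pipeline level while tests can assert the
specific failure.
"""


class EnmdynError(Exception):
    """Base class for all errors raised by enmdyn."""


class PDBParseError(EnmdynError, ValueError):
    """Malformed or unusable PDB input (no CA atoms, duplicate records...)."""


class EmptySelectionError(EnmdynError, ValueError):
    """A chain or bead selection matched nothing."""


class TrajectoryFormatError(EnmdynError, ValueError):
    """Malformed trajectory file (truncated frame, inconsistent bead count)."""


class DomainError(EnmdynError, ValueError):
    """Unresolvable or overlapping domain definitions."""


class ParameterError(EnmdynError, ValueError):
    """Invalid model or simulation parameter."""


class ShapeError(EnmdynError, ValueError):
    """Array shape does not match the model/network it is used with."""


class SingularGeometryError(EnmdynError, ValueError):
    """Coincident bonded beads make forces undefined."""


class IntegrationError(EnmdynError, RuntimeError):
    """Time step unstable or trajectory diverged."""


class UnsuperposedTrajectoryError(EnmdynError, ValueError):
    """Operation requires a trajectory that went through superpose() first."""


class DegenerateSelectionError(EnmdynError, ValueError):
    """Fit selection too small or collinear for a unique rotation."""


class UndefinedOverlapError(EnmdynError, ValueError):
    """Overlap requested between fields that vanish on the selection."""


class ZeroVarianceError(EnmdynError, ValueError):
    """Normalization of a constant profile is undefined."""


class GenerationError(EnmdynError, RuntimeError):
    """Synthetic structure generation failed (self-avoidance unsatisfiable)."""


class PipelineError(EnmdynError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
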