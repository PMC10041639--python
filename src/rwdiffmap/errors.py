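"""Exception types shared across the package."""


class RwDiffMapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RwDiffMapError, ValueError):
    """Invalid input data or configuration."""


class DegenerateSubspaceError(RwDiffMapError, ValueError):
    """A variable subspace whose median pairwise distance is zero.

    The Gaussian-kernel scale constant is the median of all pairwise
    Euclidean distances in the active subspace; a zero median (all samples
    coincide in that subspace) leaves the kernel undefined.  The offending
    subspace is reported rather than silently substituting a bandwidth.
    """

    def __init__(self, subset, message: str | None = None):
        self.subset = tuple(subset) if subset is not None else None
        if message is None:
            message = (
                "median pairwise distance is zero in variable subspace "
                f"{self.subset}; the kernel scale constant is undefined"
            )
        super().__init__(message)


class EigenSolverError(RwDiffMapError, RuntimeError):
    """The symmetric eigensolver failed to converge."""
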