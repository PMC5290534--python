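"""Exception types shared across the pipeline."""


class MTBMError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MTBMError):
    """A surface file is malformed or lacks required grid metadata."""


class ValidationError(MTBMError, ValueError):
    """Input data violates a documented invariant."""


class DegenerateCellError(ValidationError):
    """A grid cell has (near-)zero area or collinear edges."""

    def __init__(self, ring: int, around: int, detail: str = ""):
        self.ring = ring
        self.around = around
        msg = f"degenerate cell at (ring={ring}, around={around})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class FoldError(MTBMError):
    """A parameter map or deformation folds (non-injective)."""

    def __init__(self, ring: int, around: int, detail: str = ""):
        self.ring = ring
        self.around = around
        msg = f"folded cell at (ring={ring}, around={around})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class ConvergenceError(MTBMError):
    """An iterative solve failed to reach tolerance."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"solver did not converge: final residual {residual:.3e} > tol {tol:.3e}"
        )


class DomainError(MTBMError, ValueError):
    """A numerical operation was called outside its mathematical domain."""


class GenerationError(MTBMError):
    """Synthetic cohort generation produced an invalid (folded) surface."""
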