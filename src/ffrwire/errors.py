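"""Package-specific error signals."""


class OcclusionError(ValueError):
    """The guidewire (or a degenerate section) leaves no open flow area."""


class ConvergenceError(RuntimeError):
    """The quasi-steady flow solve failed at a time step.

    Carries the offending time and the last residual so a failed pulsatile
    run can be diagnosed without re-running it.
    """

    def __init__(self, message: str, *, time: float | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.time = time
        self.residual = residual
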