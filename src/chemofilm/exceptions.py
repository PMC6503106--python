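"""Exception types shared across the package."""


class WashoutError(ValueError):
    """No planktonic steady state exists at the requested dilution rate."""


class EstimationError(RuntimeError):
    """A parameter fit could not produce a valid estimate."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a trajectory."""
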