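"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model parameter, grid, or configuration value violates its constraints."""


class NumericalError(RuntimeError):
    """Numerical integration or root finding produced an invalid state."""
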