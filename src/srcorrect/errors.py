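"""Exception types shared across the pipeline."""


class GeometryError(ValueError):
    """Sensor ring, grid, or source placement is geometrically inconsistent."""


class ConfigurationError(ValueError):
    """A configuration value is invalid (unstable time step, bad filter band, ...)."""


class ShapeError(ValueError):
    """Array shapes do not satisfy an operation's contract."""
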