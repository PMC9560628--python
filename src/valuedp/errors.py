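"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


class NumericalError(RuntimeError):
    """Non-finite values encountered during backward induction."""


class CalibrationError(RuntimeError):
    """Reward-rate calibration could not bracket a fixed point."""
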