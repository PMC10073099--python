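"""Exception hierarchy for cABC analysis."""


class CabcError(Exception):
    """Base class for all cABC errors."""


class NegativeValueError(CabcError):
    """An item carries a negative value; ABC analysis is defined on non-negative data."""

    def __init__(self, label, value):
        self.label = label
        self.value = value
        super().__init__(f"item {label!r} has negative value {value!r}; "
                         "ABC analysis requires non-negative items")


class DegenerateInputError(CabcError):
    """All item values are zero — no yield can be distributed."""


class TooFewItemsError(CabcError):
    """Fewer than three items; an ABC curve cannot be constructed."""


class NonMonotoneInterpolantError(CabcError):
    """The fitted interpolant is not monotone (spline overshoot).

    Use shape-preserving interpolation (``interpolation="pchip"``) instead.
    """


class StratificationError(CabcError):
    """A class has too few cases for a stratified split."""


class ConfigError(CabcError):
    """Invalid configuration value."""


class SchemaError(CabcError):
    """A file does not conform to the expected CSV/JSON schema."""
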