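"""Exception hierarchy for the dqii package.

Every error raised by the library derives from :class:`DQIIError`, so callers
(and the CLI) can catch one type and report stage-named messages.
"""


class DQIIError(Exception):
    """Base class for all dqii errors."""


class SchemaError(DQIIError):
    """A tabular input is missing or carries unknown columns/fields."""


class ValidationError(DQIIError):
    """A value violates a domain invariant (negative nutrient, bad enum...)."""


class DuplicateFoodError(ValidationError):
    """A food table contains a repeated food_id."""


class FoodLookupError(DQIIError, KeyError):
    """A food_id does not resolve in the food table."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class ConfigError(DQIIError):
    """A scoring configuration is unsupported or internally inconsistent."""


class FeasibilityError(DQIIError):
    """A synthetic plan specification cannot be realised with the food table."""


class DegenerateDataError(DQIIError):
    """A statistical routine received data with no usable variation."""
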