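"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A domain object or scenario config failed validation.

    The message names the offending field(s) so that config errors are
    actionable from the command line.
    """


class ScenarioParseError(ValidationError):
    """A scenario file could not be parsed into a valid scenario."""
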