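"""Exception hierarchy shared by all stages."""


class AgescreenError(Exception):
    """Base class for all package errors."""


class FormatError(AgescreenError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(AgescreenError, ValueError):
    """Parsed data violates a domain invariant (e.g. beta value outside [0, 1])."""


class ConfigError(AgescreenError, ValueError):
    """An invalid parameter or simulation/pipeline configuration."""


class InputError(AgescreenError, ValueError):
    """Inputs are structurally valid but unusable (e.g. too few shared samples)."""
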