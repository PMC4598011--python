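"""Exception hierarchy for glymphsim."""


class GlymphsimError(Exception):
    """Base class for all glymphsim errors."""


class ParameterError(GlymphsimError, ValueError):
    """A parameter value violates its declared domain or invariants."""


class ConfigError(GlymphsimError, ValueError):
    """A run-configuration file is malformed or contains unknown keys."""


class InvariantError(GlymphsimError, RuntimeError):
    """An internal model invariant was violated during simulation."""
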