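"""Exception hierarchy for panel loading and analysis."""


class DynacytError(Exception):
    """Base class for all package errors."""


class PanelFormatError(DynacytError):
    """The input file does not conform to the expected CSV layout."""


class PanelIntegrityError(DynacytError):
    """The data violate a structural invariant of the study design."""


class DomainError(DynacytError):
    """A value is outside its permitted domain (e.g. negative concentration)."""


class ConfigError(DynacytError):
    """A synthetic-data or pipeline configuration is inconsistent."""


class AnalysisError(DynacytError):
    """An analysis stage cannot proceed on the given panel."""
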