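"""Exception hierarchy for the lncage pipeline."""


class LncageError(Exception):
    """Base class for all lncage errors."""


class ConfigError(LncageError):
    """Invalid study or pipeline configuration."""


class InputError(LncageError):
    """Malformed or inconsistent input files / tables."""


class AnalysisError(LncageError):
    """A statistical stage received input it cannot analyse."""
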