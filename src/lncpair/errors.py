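"""Exception hierarchy for the lncpair pipeline."""


class LncPairError(Exception):
    """Base class for all lncpair errors."""


class FormatError(LncPairError):
    """An on-disk input violates its format contract (duplicates, ragged rows, bad values)."""


class ConfigurationError(LncPairError):
    """A parameter or configuration value is outside its documented domain."""


class PipelineError(LncPairError):
    """A stage cannot proceed (empty partition, no admissible cutoff, fit failure)."""
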