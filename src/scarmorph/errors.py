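"""Exception hierarchy for the scarmorph pipeline."""


class ScarmorphError(Exception):
    """Base class for all scarmorph-specific failures."""


class ParameterError(ScarmorphError, ValueError):
    """An invalid parameter value or configuration."""


class ImageFormatError(ScarmorphError, ValueError):
    """A file that is not a readable single-channel image."""


class ManifestError(ScarmorphError, ValueError):
    """A cohort manifest that is missing, malformed, or inconsistent."""
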