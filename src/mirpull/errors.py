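"""Exception hierarchy for mirpull."""


class MirpullError(Exception):
    """Base class for all mirpull errors."""


class ConfigError(MirpullError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(MirpullError):
    """A malformed input file; the message carries row/column location."""


class DesignError(MirpullError):
    """An inconsistent sample design (missing or duplicated arm/miRNA/replicate)."""
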