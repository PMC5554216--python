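class SiteoccError(Exception):
    """Base class for all siteocc errors."""


class ConfigurationError(SiteoccError):
    """A schema/config problem: missing column mapping, bad option value."""


class DataError(SiteoccError):
    """The input data violate a contract (duplicates, unparseable rows, ...)."""
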