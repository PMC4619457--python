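"""Exception hierarchy for adrproxy."""


class AdrProxyError(Exception):
    """Base class for all adrproxy errors."""


class InputError(AdrProxyError, ValueError):
    """A single value or record violates its invariants."""


class DataIntegrityError(AdrProxyError):
    """Cross-table referential integrity is broken (e.g. a dispensing for a
    patient with no follow-up record)."""


class ConfigError(AdrProxyError):
    """A run configuration or simulation parameter set is inconsistent."""


class UndefinedEstimateError(AdrProxyError):
    """A proportion was requested with a zero denominator or an unsupported
    ascertainment level."""


class LoadError(AdrProxyError):
    """A CSV input failed schema validation; message names the file and row."""
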