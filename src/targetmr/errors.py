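"""Exception types shared across the package."""


class SchemaError(ValueError):
    """An input table is missing a mandatory column or has an unusable layout."""


class DuplicateVariantError(ValueError):
    """The same variant identifier appears more than once within one trait."""


class NoInstrumentsError(RuntimeError):
    """Instrument selection for a target produced an empty set."""


class NoOverlapError(RuntimeError):
    """Two traits share no variants in the requested region."""
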