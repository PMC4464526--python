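"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input table, record or configuration violates a documented invariant.

    Messages always name the offending table/row/field so that malformed
    inputs are reported rather than silently dropped.
    """
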