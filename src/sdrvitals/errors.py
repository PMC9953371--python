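"""Exceptions shared across the package."""


class NoRateDetected(RuntimeError):
    """Raised when no spectral peak rises far enough above the in-band noise floor.

    Streaming estimators catch this and emit a missing value (NaN) for the
    affected update tick; batch callers may want to handle it explicitly.
    """
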