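"""Exception types raised by the pipeline."""


class PingFilterError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(PingFilterError):
    """A configuration value violates its invariants."""


class NoDetectionFilesError(PingFilterError):
    """No raw detection files matched the requested extension."""


class TimestampParseError(PingFilterError):
    """One or more timestamps failed every candidate format.

    Carries the offending file, 1-based row numbers and raw strings so the
    user can fix the format list instead of silently losing rows.
    """

    def __init__(self, source: str, rows, values, formats):
        self.source = source
        self.rows = list(rows)
        self.values = list(values)
        self.formats = list(formats)
        shown = ", ".join(
            f"row {r}: {v!r}" for r, v in zip(self.rows[:10], self.values[:10])
        )
        more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
        super().__init__(
            f"{source}: {len(self.rows)} timestamp(s) failed all formats "
            f"{self.formats}: {shown}{more}"
        )


class ValidationError(PingFilterError):
    """A metadata table violates its invariants (overlapping deployments,
    unknown stations, asymmetric distance matrix, ...)."""
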