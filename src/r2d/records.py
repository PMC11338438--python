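"""The shared input record type: one RNA feature site in transcript coordinates."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SiteRecord"]


@dataclass(frozen=True)
class SiteRecord:
    """One BED3+ feature on a transcript.

    ``extra_columns`` (BED columns 4..n) are opaque strings preserved
    byte-identically through every downstream operation.
    """

    tx_id: str
    tx_start: int  # 0-based inclusive
    tx_end: int    # exclusive
    extra_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"invalid site interval [{self.tx_start}, {self.tx_end})")

    def fields(self) -> tuple[str, ...]:
        """The original input columns, verbatim."""
        return (self.tx_id, str(self.tx_start), str(self.tx_end)) + self.extra_columns
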