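"""Closed integer-year age bands and the standard demographic 5-year grid.

Bands are closed intervals of whole years of age: the band 15-19 contains
ages 15, 16, 17, 18 and 19 and has width 5.  An open-ended band such as
``80+`` is encoded with an explicit flag (``upper is None``), never with a
sentinel age.  The standard grid is the 21-band layout used by the US Census
Bureau International Data Base: 0-4, 5-9, ..., 95-99, 100+.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError, ValidationError

#: Width assumed for the open-ended terminal band (100+) wherever a finite
#: width is needed, e.g. median-age interpolation.
OPEN_BAND_NOMINAL_WIDTH = 5


@dataclass(frozen=True, order=True)
class AgeBand:
    """Closed age interval ``[lower, upper]`` in whole years.

    ``upper is None`` marks an open-ended band (e.g. ``80+``).
    """

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValidationError(f"age band lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ValidationError(
                f"age band upper bound {self.upper} below lower bound {self.lower}"
            )

    @property
    def open_ended(self) -> bool:
        return self.upper is None

    @property
    def width(self) -> int:
        """Number of whole years covered; open bands use the nominal width."""
        if self.upper is None:
            return OPEN_BAND_NOMINAL_WIDTH
        return self.upper - self.lower + 1

    def overlap_years(self, other: "AgeBand") -> int:
        """Count of whole years of age contained in both bands.

        Two open-ended bands overlap over the nominal width beyond the later
        start; an open band against a bounded band is truncated at the
        bounded band's limits.
        """
        lo = max(self.lower, other.lower)
        if self.upper is None and other.upper is None:
            return OPEN_BAND_NOMINAL_WIDTH
        if self.upper is None:
            hi = other.upper
        elif other.upper is None:
            hi = self.upper
        else:
            hi = min(self.upper, other.upper)
        assert hi is not None
        return max(0, hi - lo + 1)

    def overlaps(self, other: "AgeBand") -> bool:
        if self.upper is None and other.upper is None:
            return True
        if self.upper is None:
            return other.upper >= self.lower
        if other.upper is None:
            return self.upper >= other.lower
        return self.lower <= other.upper and other.lower <= self.upper

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper}"

    @classmethod
    def from_label(cls, label: str) -> "AgeBand":
        """Parse ``"15-19"`` or ``"100+"`` (IDB GROUP dialect)."""
        text = str(label).strip()
        if text.endswith("+"):
            try:
                return cls(int(text[:-1]))
            except ValueError:
                raise FormatError(f"unparseable age band label {label!r}") from None
        for sep in ("-", "–", " to "):
            if sep in text:
                lo_s, _, hi_s = text.partition(sep)
                try:
                    return cls(int(lo_s), int(hi_s))
                except ValueError:
                    raise FormatError(f"unparseable age band label {label!r}") from None
        raise FormatError(f"unparseable age band label {label!r}")

    @classmethod
    def from_bounds(cls, lo, hi) -> "AgeBand":
        """Build from lo/hi cells where a blank, NaN or '+'-suffixed hi is open."""
        import math

        if hi is None or (isinstance(hi, float) and math.isnan(hi)):
            return cls(int(lo))
        hi_s = str(hi).strip()
        if hi_s in ("", "+"):
            return cls(int(lo))
        if hi_s.endswith("+"):
            return cls(int(float(hi_s[:-1])))
        return cls(int(lo), int(float(hi_s)))


#: The standard 21-band demographic grid: 0-4, 5-9, ..., 95-99, 100+.
STANDARD_GRID: tuple[AgeBand, ...] = tuple(
    [AgeBand(lo, lo + 4) for lo in range(0, 100, 5)] + [AgeBand(100)]
)


def validate_band_sequence(bands: list[AgeBand], context: str = "") -> None:
    """Check bands are sorted ascending, non-overlapping, with at most one
    open-ended band which must be the oldest.  Raises ValidationError."""
    where = f" in {context}" if context else ""
    for a, b in zip(bands, bands[1:]):
        if a.open_ended:
            raise ValidationError(f"open-ended band {a.label} is not the oldest{where}")
        if b.lower <= (a.upper if a.upper is not None else b.lower):
            if a.overlaps(b):
                raise ValidationError(f"bands {a.label} and {b.label} overlap{where}")
            raise ValidationError(f"bands {a.label} and {b.label} out of order{where}")
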