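"""Five-year age bands for incidence tables.

Rates, populations, mortality and ratio tables all share one band ladder,
by default 50-54, 55-59, ..., 80-84, 85+ (the terminal band is open-ended).
Band assignment uses age in completed years at the event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional


@dataclass(frozen=True)
class AgeBand:
    """Half-open age interval [lower, upper); ``upper=None`` means open-ended."""

    lower: int
    upper: Optional[int] = None

    def __post_init__(self) -> None:
        if self.upper is not None and self.upper <= self.lower:
            raise ValueError(f"band upper {self.upper} must exceed lower {self.lower}")

    def contains(self, age: int) -> bool:
        if age < self.lower:
            return False
        return self.upper is None or age < self.upper

    @property
    def midpoint(self) -> float:
        """Band midpoint in years; the open terminal band uses lower + 2.5."""
        if self.upper is None:
            return self.lower + 2.5
        return (self.lower + self.upper) / 2.0

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper - 1}"

    def __lt__(self, other: "AgeBand") -> bool:  # open band sorts by lower bound
        return self.lower < other.lower


#: The default ladder used throughout: 5-year intervals from 50 with open 85+.
DEFAULT_BANDS: tuple[AgeBand, ...] = tuple(
    [AgeBand(lo, lo + 5) for lo in range(50, 85, 5)] + [AgeBand(85, None)]
)

SEXES = ("female", "male")


def assign_band(age: int, bands: Iterable[AgeBand] = DEFAULT_BANDS) -> AgeBand:
    """Return the band containing ``age``.

    Raises ``ValueError`` when the age falls below the ladder (such a case
    should already have been removed by the registry filter).
    """
    for band in bands:
        if band.contains(age):
            return band
    raise ValueError(f"age {age} is below the band ladder")


def bands_from_frame(df) -> list[AgeBand]:
    """Extract the sorted, de-duplicated ladder from a table with
    ``band_lower`` / ``band_upper`` columns (NaN upper = open band)."""
    import pandas as pd

    seen = set()
    for lo, up in zip(df["band_lower"], df["band_upper"]):
        up_val = None if pd.isna(up) else int(up)
        seen.add(AgeBand(int(lo), up_val))
    return sorted(seen)


def same_ladder(a: Iterable[AgeBand], b: Iterable[AgeBand]) -> bool:
    return sorted(a) == sorted(b)
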