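"""Screening-campaign bookkeeping and Kyte-Doolittle hydropathy profiles.

Two small, self-contained utilities used around the structural and kinetic
analyses: hit-rate accounting for a two-library virtual/in-vitro screening
funnel (compounds docked -> selected for purchase -> active in the assay),
and per-residue hydropathy profiling of a protein sequence on the
Kyte-Doolittle scale, the scalar that hydrophobicity surface colourings
are built from.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "KYTE_DOOLITTLE",
    "ScreenSummary",
    "HydropathyProfile",
    "hit_rate",
    "format_rate",
    "hydropathy_profile",
    "summarize_screen",
]

#: Kyte & Doolittle (1982) hydropathy values, one per standard amino acid.
#: Embedded as the single source of truth; spans -4.5 (Arg) to +4.5 (Ile).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hit_rate(n_hits: int, n_total: int) -> float:
    """Percentage of hits among ``n_total``, unrounded.

    For a virtual screen this is compounds-selected / compounds-docked;
    for an in-vitro screen, actives / compounds-tested.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_hits <= n_total:
        raise ValueError(f"n_hits must be in [0, {n_total}], got {n_hits}")
    return 100.0 * n_hits / n_total


def format_rate(rate_percent: float, decimals: int = 2) -> str:
    """Display form of a percentage: half-up rounding to ``decimals``."""
    q = Decimal(1).scaleb(-decimals)
    return f"{Decimal(repr(rate_percent)).quantize(q, rounding=ROUND_HALF_UP)}%"


@dataclass
class ScreenSummary:
    """Per-library (or pooled) screening funnel counts and hit rates."""

    library_name: str
    n_docked: int
    n_selected: int
    n_active: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_active <= self.n_selected <= self.n_docked:
            raise ValueError(
                f"{self.library_name}: need 0 <= active ({self.n_active}) <= "
                f"selected ({self.n_selected}) <= docked ({self.n_docked})"
            )

    @property
    def virtual_hit_rate(self) -> float:
        return hit_rate(self.n_selected, self.n_docked)

    @property
    def invitro_hit_rate(self) -> float:
        """Actives among tested compounds; NaN when nothing was tested."""
        if self.n_selected == 0:
            return float("nan")
        return hit_rate(self.n_active, self.n_selected)

    def as_dict(self) -> dict:
        return {
            "library": self.library_name,
            "n_docked": self.n_docked,
            "n_selected": self.n_selected,
            "n_active": self.n_active,
            "virtual_hit_rate": self.virtual_hit_rate,
            "virtual_hit_rate_display": format_rate(self.virtual_hit_rate),
            "invitro_hit_rate": self.invitro_hit_rate,
            "invitro_hit_rate_display": (
                format_rate(self.invitro_hit_rate) if self.n_selected else "n/a"
            ),
        }


def summarize_screen(records: pd.DataFrame, pooled_label: str = "ALL") -> list[ScreenSummary]:
    """Aggregate a compound table into per-library and pooled summaries.

    ``records`` needs columns ``library`` (str), ``selected`` and
    ``active`` (boolean or 0/1); each row is one docked compound. The
    pooled row sums every library and is appended last.
    """
    required = {"library", "selected", "active"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"screen table is missing columns: {sorted(missing)}")
    if len(records) == 0:
        return []
    bad = records[records["active"].astype(bool) & ~records["selected"].astype(bool)]
    if len(bad):
        raise ValueError(f"{len(bad)} compound(s) marked active but not selected")
    out: list[ScreenSummary] = []
    for lib, grp in records.groupby("library", sort=False):
        out.append(
            ScreenSummary(
                library_name=str(lib),
                n_docked=len(grp),
                n_selected=int(grp["selected"].astype(bool).sum()),
                n_active=int(grp["active"].astype(bool).sum()),
            )
        )
    out.append(
        ScreenSummary(
            library_name=pooled_label,
            n_docked=len(records),
            n_selected=int(records["selected"].astype(bool).sum()),
            n_active=int(records["active"].astype(bool).sum()),
        )
    )
    return out


@dataclass
class HydropathyProfile:
    """Per-residue hydropathy values and their sliding-window means."""

    sequence: str
    window: int
    values: np.ndarray  # raw per-residue scale values
    smoothed: np.ndarray  # centred window means; NaN within half-window of the ends

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.sequence) + 1),
                "residue": list(self.sequence),
                "hydropathy": self.values,
                "smoothed": self.smoothed,
            }
        )


def hydropathy_profile(sequence: str, window: int = 9) -> HydropathyProfile:
    """Kyte-Doolittle hydropathy of ``sequence`` with a centred window mean.

    ``window`` must be odd; positions closer than half a window to either
    terminus have no smoothed value (NaN), matching the usual profile
    convention. Raises on any non-standard residue letter, naming the
    offending position.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    seq = sequence.upper()
    values = np.empty(len(seq))
    for i, aa in enumerate(seq):
        try:
            values[i] = KYTE_DOOLITTLE[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {i + 1}"
            ) from None
    half = window // 2
    smoothed = np.full(len(seq), np.nan)
    if len(seq) >= window:
        kernel = np.ones(window) / window
        smoothed[half : len(seq) - half] = np.convolve(values, kernel, mode="valid")
    return HydropathyProfile(sequence=seq, window=window, values=values, smoothed=smoothed)
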