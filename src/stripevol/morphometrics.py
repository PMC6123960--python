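"""Morphometric indexes for dorsal-fin shape and body elongation.

The dorsal-fin lobe indexes quantify the indentation between the anterior
(spiny) and posterior (soft-rayed) lobes from four linear measurements per
specimen: l1, the length of the third dorsal spine; l2, the length of the
most posterior spine; lr, the length of the longest soft ray; and L, the
length of the dorsal fin, used for normalization.  Elongation is body height
over standard length.  All indexes are dimensionless and invariant to a
common rescaling of the measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "FinMeasurements",
    "BodyMeasurements",
    "anterior_lobe_index",
    "posterior_lobe_index",
    "elongation",
    "read_trait_table",
    "compute_indexes",
]

#: Expected columns of the species trait table.
TRAIT_COLUMNS = ("species", "stripes", "l1", "l2", "lr", "L", "height", "SL",
                 "max_size", "n_hosts")


@dataclass(frozen=True)
class FinMeasurements:
    l1: float   # third dorsal spine
    l2: float   # most posterior spine
    lr: float   # longest soft ray
    L: float    # dorsal fin length (normalizer)

    def __post_init__(self) -> None:
        if min(self.l1, self.l2, self.lr, self.L) <= 0:
            raise ValueError("fin measurements must all be > 0")


@dataclass(frozen=True)
class BodyMeasurements:
    height: float
    standard_length: float
    max_size: float | None = None

    def __post_init__(self) -> None:
        if self.height <= 0 or self.standard_length <= 0:
            raise ValueError("body measurements must be > 0")


def anterior_lobe_index(m: FinMeasurements) -> float:
    """(l1 - l2) / L — negative values are allowed (no anterior indentation)."""
    if m.L <= 0:
        raise ValueError("dorsal fin length L must be > 0")
    return (m.l1 - m.l2) / m.L


def posterior_lobe_index(m: FinMeasurements) -> float:
    """(lr - l2) / L."""
    if m.L <= 0:
        raise ValueError("dorsal fin length L must be > 0")
    return (m.lr - m.l2) / m.L


def elongation(b: BodyMeasurements) -> float:
    """Body height over standard length."""
    if b.standard_length <= 0:
        raise ValueError("standard length must be > 0")
    return b.height / b.standard_length


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read the species trait TSV (mandatory ``species`` column).

    Missing measurements may be blank; rows are dropped per-regression, not
    here.
    """
    df = pd.read_csv(path, sep="\t")
    if "species" not in df.columns:
        raise ValueError("trait table requires a 'species' column")
    return df


def compute_indexes(df: pd.DataFrame) -> pd.DataFrame:
    """Append anterior/posterior lobe indexes and elongation to a trait table."""
    out = df.copy()
    out["anterior_index"] = (out["l1"] - out["l2"]) / out["L"]
    out["posterior_index"] = (out["lr"] - out["l2"]) / out["L"]
    out["elongation"] = out["height"] / out["SL"]
    return out
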