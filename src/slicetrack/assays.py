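"""Closed-form assay computations: specific lysis and caliper tumor volume."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AssayMeasurement", "specific_lysis", "specific_lysis_table", "tumor_volume"]

_MODALITIES = ("bioluminescence", "chromium")


@dataclass
class AssayMeasurement:
    """One cytotoxicity well with its spontaneous and maximum controls.

    For bioluminescence, live target cells emit light, so the spontaneous
    control exceeds the maximum-killing control; for chromium release the
    ordering is reversed (lysed cells release more 51Cr).
    """

    test: float
    spontaneous: float
    maximum: float
    modality: str = "bioluminescence"

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")
        for name in ("test", "spontaneous", "maximum"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} signal must be >= 0")
        if self.modality == "bioluminescence" and self.spontaneous < self.maximum:
            raise ValueError(
                "bioluminescence assay requires spontaneous >= maximum "
                "(live cells emit more light than lysed cells)"
            )
        if self.modality == "chromium" and self.maximum < self.spontaneous:
            raise ValueError(
                "chromium-release assay requires maximum >= spontaneous "
                "(lysed cells release more 51Cr)"
            )


def specific_lysis(measurement: AssayMeasurement) -> float:
    """Percent specific lysis normalized to the assay window.

    bioluminescence: ``100 * (spontaneous - test) / (spontaneous - maximum)``;
    chromium release: ``100 * (test - spontaneous) / (maximum - spontaneous)``.
    Both return 0% at the spontaneous control and 100% at the maximum
    control.  Results outside [-25, 125] are kept but flagged with a warning.
    """
    m = measurement
    if m.modality == "bioluminescence":
        denom = m.spontaneous - m.maximum
        numer = m.spontaneous - m.test
    else:
        denom = m.maximum - m.spontaneous
        numer = m.test - m.spontaneous
    if denom == 0:
        raise ValueError("assay window is zero (spontaneous == maximum control)")
    pct = 100.0 * numer / denom
    if not -25.0 <= pct <= 125.0:
        warnings.warn(f"specific lysis of {pct:.1f}% is outside [-25, 125]%", stacklevel=2)
    return pct


def specific_lysis_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``specific_lysis_pct`` column to a per-well table.

    Expects columns ``sample``, ``modality``, ``test``, ``spontaneous``,
    ``maximum``.
    """
    required = {"sample", "modality", "test", "spontaneous", "maximum"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    out["specific_lysis_pct"] = [
        specific_lysis(
            AssayMeasurement(
                test=row.test, spontaneous=row.spontaneous, maximum=row.maximum, modality=row.modality
            )
        )
        for row in df.itertuples()
    ]
    return out


def tumor_volume(radius_mm: float) -> float:
    """Spherical caliper volume, ``V = 4/3 * pi * r^3`` (mm^3)."""
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    return 4.0 / 3.0 * np.pi * radius_mm**3
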