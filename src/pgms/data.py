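"""Paired blood-glucose readings and their CSV round-trip.

The universal input everywhere in this package is a sequence of paired
readings ``(y, x)``: a reference invasive value ``y`` (finger-prick blood
sample) and a non-invasive measured value ``x`` (skin-contact sensor),
both in mg/dl.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CSV_COLUMNS = ("invasive_mgdl", "noninvasive_mgdl")


class DataError(ValueError):
    """Malformed or physiologically impossible input data."""


@dataclass
class PairedDataset:
    """Paired (invasive reference, non-invasive measured) glucose readings.

    Parameters
    ----------
    invasive : array of float
        Reference values y_i in mg/dl, strictly positive.
    noninvasive : array of float
        Measured values x_i in mg/dl, strictly positive.
    provenance : dict
        Free-form record of how the data came to be (generator spec,
        seed, clipped indices, ...).
    """

    invasive: np.ndarray
    noninvasive: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.invasive = np.asarray(self.invasive, dtype=float)
        self.noninvasive = np.asarray(self.noninvasive, dtype=float)
        if self.invasive.shape != self.noninvasive.shape or self.invasive.ndim != 1:
            raise DataError("invasive and noninvasive must be 1-D and equal length")
        if self.invasive.size and (
            np.any(self.invasive <= 0) or np.any(self.noninvasive <= 0)
        ):
            bad = int(
                np.argmax((self.invasive <= 0) | (self.noninvasive <= 0))
            )
            raise DataError(f"non-positive glucose reading at row {bad}")

    def __len__(self) -> int:
        return int(self.invasive.size)

    @property
    def difference(self) -> np.ndarray:
        """Additive error d_i = y_i - x_i in mg/dl (the boosting target)."""
        return self.invasive - self.noninvasive

    def subset(self, index: np.ndarray) -> "PairedDataset":
        return PairedDataset(
            self.invasive[index], self.noninvasive[index], dict(self.provenance)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {CSV_COLUMNS[0]: self.invasive, CSV_COLUMNS[1]: self.noninvasive}
        )


def write_paired_csv(data: PairedDataset, path) -> None:
    """Write the two-column ``invasive_mgdl,noninvasive_mgdl`` CSV."""
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_paired_csv(path) -> PairedDataset:
    """Read a paired-readings CSV, validating columns and positivity."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as a data error
        raise DataError(f"cannot parse {path}: {exc}") from exc
    for col in CSV_COLUMNS:
        if col not in frame.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    sub = frame[list(CSV_COLUMNS)]
    for col in CSV_COLUMNS:
        numeric = pd.to_numeric(sub[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise DataError(f"{path}: non-numeric value in {col!r} at row {row}")
    if len(sub) == 0:
        raise DataError(f"{path}: no data rows")
    data = PairedDataset(
        sub[CSV_COLUMNS[0]].to_numpy(float),
        sub[CSV_COLUMNS[1]].to_numpy(float),
        {"source": str(path)},
    )
    return data
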