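"""Blank-control detection thresholds and imputation.

Detection is called per metabolite against instrument blanks: the
threshold is ``max(snr x blank statistic, floor)`` with snr = 3 and a
floor of 10,000 a.u. by default. A study cell at or above its metabolite
threshold counts as detected. Two imputed study matrices are produced:
the threshold-imputed variant (non-detected cells hold the threshold, so
fold changes on them are bounds) and the zero-imputed variant used by
count-model downstream analyses. Blank columns are excluded from both.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .extraction import IntensityMatrix

__all__ = ["NoBlankColumnsError", "BlankCorrectedMatrix", "detection_threshold", "blank_correct", "zero_impute"]


class NoBlankColumnsError(ValueError):
    """Raised when blank correction is requested without blank columns."""


def detection_threshold(
    blank_heights: Sequence[float] | np.ndarray,
    snr: float = 3.0,
    floor: float = 10000.0,
    stat: str = "mean",
) -> float:
    """Per-metabolite detection threshold: max(snr x blank stat, floor).

    ``stat`` is 'mean' (default) or 'max' (stricter). With no blank
    signal at all the threshold is the floor.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    blanks = np.asarray(blank_heights, dtype=float)
    if blanks.size == 0:
        raise NoBlankColumnsError(
            "no blank measurements: blank-based detection needs >= 1 blank column "
            "(pass floor_only=True to blank_correct for floor-only thresholds)"
        )
    if (blanks < 0).any():
        raise ValueError("blank heights must be >= 0")
    if stat == "mean":
        level = float(blanks.mean())
    elif stat == "max":
        level = float(blanks.max())
    else:
        raise ValueError(f"blank statistic must be 'mean' or 'max', got {stat!r}")
    return max(snr * level, floor)


@dataclass
class BlankCorrectedMatrix:
    """Detection-called study matrix.

    thresholds : per-metabolite detection threshold (a.u.).
    detected : boolean flags, metabolites x study samples.
    imputed : raw height where detected, threshold where not.
    zero_imputed : raw height where detected, zero where not.
    """

    thresholds: pd.Series
    detected: pd.DataFrame
    imputed: pd.DataFrame
    zero_imputed: pd.DataFrame
    samples: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "blank_corrected": outdir / "blank_corrected.tsv",
            "zero_imputed": outdir / "zero_imputed.tsv",
            "detection_flags": outdir / "detection_flags.tsv",
            "thresholds": outdir / "thresholds.tsv",
        }
        self.imputed.rename_axis("metabolite").to_csv(paths["blank_corrected"], sep="\t")
        self.zero_imputed.rename_axis("metabolite").to_csv(paths["zero_imputed"], sep="\t")
        self.detected.rename_axis("metabolite").to_csv(paths["detection_flags"], sep="\t")
        self.thresholds.rename_axis("metabolite").rename("threshold").to_csv(paths["thresholds"], sep="\t")
        return paths


def blank_correct(
    matrix: IntensityMatrix,
    snr: float = 3.0,
    floor: float = 10000.0,
    stat: str = "mean",
    floor_only: bool = False,
) -> BlankCorrectedMatrix:
    """Call detection per cell against blank-derived thresholds.

    A study cell is detected when its raw height is >= its metabolite's
    threshold (boundary inclusive). ``floor_only=True`` ignores blanks and
    thresholds everything at the floor (for designs without blank runs).
    """
    heights = matrix.heights
    if (heights.to_numpy() < 0).any():
        raise ValueError("negative heights in intensity matrix")
    study_cols = matrix.study_columns
    blank_cols = matrix.blank_columns
    if floor_only:
        thresholds = pd.Series(float(floor), index=heights.index)
    else:
        if not blank_cols:
            raise NoBlankColumnsError(
                "intensity matrix has no blank columns; blank-based detection needs >= 1 "
                "blank run, or pass floor_only=True to threshold at the floor alone"
            )
        thresholds = heights[blank_cols].apply(
            lambda row: detection_threshold(row.to_numpy(), snr=snr, floor=floor, stat=stat), axis=1
        )
    study = heights[study_cols]
    detected = study.ge(thresholds, axis=0)
    imputed = study.where(detected, thresholds, axis=0)
    zero_imputed = study.where(detected, 0.0)
    samples = matrix.samples.loc[study_cols]
    return BlankCorrectedMatrix(thresholds, detected, imputed, zero_imputed, samples)


def zero_impute(corrected: BlankCorrectedMatrix) -> pd.DataFrame:
    """Zero-imputed study matrix (raw where detected, 0 where not)."""
    return corrected.zero_imputed.copy()
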