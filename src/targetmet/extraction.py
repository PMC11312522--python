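"""Targeted peak extraction from centroided LC-MS runs.

One peak height per (metabolite, sample): an extracted ion chromatogram
(XIC) is built inside a ppm window around the theoretical adduct m/z and
a retention-time search window around the library retention time; the
XIC apex is the quantified height. A measurement is kept only if its
apex lies within a tight apex tolerance of a reference retention time —
either the library value or, in the default two-pass scheme, the median
apex observed across study samples (the consensus apex).

Defaults follow the acquisition/processing parameters of the targeted
HILIC workflow this package models: +/-5 ppm, +/-0.5 min search window,
+/-7.5 s apex tolerance, peak height (not area) as the quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _mzml
from .chem import ElementalFormula, IonType, get_ion_type, ppm_window, theoretical_mz

__all__ = [
    "Spectrum",
    "SampleRun",
    "MetaboliteLibraryEntry",
    "ExtractionParams",
    "PeakMeasurement",
    "IntensityMatrix",
    "xic",
    "extract_peak",
    "consensus_apex",
    "build_matrix",
    "load_runs",
    "read_library",
    "read_samples",
]


@dataclass
class Spectrum:
    """One centroided MS1 scan: retention time (minutes), polarity, arrays."""

    rt: float
    polarity: str  # '+' or '-'
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = float(self.rt)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if len(self.mz) and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class SampleRun:
    """One LC-MS acquisition: time-ordered spectra plus sample metadata."""

    sample_id: str
    role: str  # 'study' or 'blank'
    group: str
    spectra: list[Spectrum]
    _rts: np.ndarray | None = field(default=None, repr=False, compare=False)
    _pols: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        rts = np.array([s.rt for s in self.spectra], dtype=float)
        if len(rts) > 1 and np.any(np.diff(rts) <= 0):
            raise ValueError(f"spectra of run {self.sample_id!r} must be strictly increasing in rt")
        self._rts = rts
        self._pols = np.array([s.polarity for s in self.spectra])

    @property
    def rts(self) -> np.ndarray:
        return self._rts

    @property
    def polarities(self) -> np.ndarray:
        return self._pols


@dataclass(frozen=True)
class MetaboliteLibraryEntry:
    """One targeted compound: name, formula, expected ion, reference RT (min)."""

    name: str
    formula: ElementalFormula
    ion: IonType
    rt_min: float


@dataclass(frozen=True)
class ExtractionParams:
    """Extraction tolerances.

    tol_ppm : mass tolerance, parts per million (default 5).
    rt_search_min : half-width of the initial RT search window, minutes
        (default 0.5).
    apex_tol_s : apex retention-time tolerance vs the reference apex,
        seconds (default 7.5).
    centroid_combine : 'sum' (default) or 'max' — how coincident
        centroids inside the m/z window contribute to an XIC point.
    consensus : two-pass consensus-apex extraction (default True);
        False uses the library RT as the apex reference in one pass.
    """

    tol_ppm: float = 5.0
    rt_search_min: float = 0.5
    apex_tol_s: float = 7.5
    centroid_combine: str = "sum"
    consensus: bool = True

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0 or self.rt_search_min <= 0 or self.apex_tol_s <= 0:
            raise ValueError("extraction tolerances must all be positive")
        if self.centroid_combine not in ("sum", "max"):
            raise ValueError("centroid_combine must be 'sum' or 'max'")

    @property
    def apex_tol_min(self) -> float:
        return self.apex_tol_s / 60.0


@dataclass
class PeakMeasurement:
    metabolite: str
    sample_id: str
    apex_rt: float | None
    height: float
    detected_raw: bool


def xic(
    run: SampleRun,
    mz_window: tuple[float, float],
    rt_window: tuple[float, float],
    polarity: str,
    combine: str = "sum",
) -> list[tuple[float, float]]:
    """Extracted ion chromatogram: one (rt, intensity) point per
    matching-polarity spectrum whose rt lies in ``rt_window``; the point's
    intensity is the sum (or max) of centroid intensities inside
    ``mz_window``, zero if none fall inside."""
    mz_lo, mz_hi = mz_window
    rt_lo, rt_hi = rt_window
    if mz_lo > mz_hi or rt_lo > rt_hi:
        raise ValueError("windows must satisfy lo <= hi")
    rts = run.rts
    if len(rts) == 0:
        return []
    i0 = int(np.searchsorted(rts, rt_lo, side="left"))
    i1 = int(np.searchsorted(rts, rt_hi, side="right"))
    trace: list[tuple[float, float]] = []
    for i in range(i0, i1):
        spec = run.spectra[i]
        if spec.polarity != polarity:
            continue
        j0 = int(np.searchsorted(spec.mz, mz_lo, side="left"))
        j1 = int(np.searchsorted(spec.mz, mz_hi, side="right"))
        if j1 > j0:
            vals = spec.intensity[j0:j1]
            inten = float(vals.sum()) if combine == "sum" else float(vals.max())
        else:
            inten = 0.0
        trace.append((spec.rt, inten))
    return trace


def extract_peak(
    run: SampleRun,
    entry: MetaboliteLibraryEntry,
    params: ExtractionParams = ExtractionParams(),
    consensus_apex_rt: float | None = None,
    iso_k: int = 0,
) -> PeakMeasurement:
    """Extract one peak height for ``entry`` from ``run``.

    The XIC is built in the +/-``rt_search_min`` window around the library
    RT using the +/-``tol_ppm`` window around the theoretical m/z of the
    m+``iso_k`` isotopologue. The apex is the maximum-intensity XIC point
    (ties broken toward the reference apex). The measurement is retained
    only if the apex lies within ``apex_tol_s`` of the reference apex
    (``consensus_apex_rt`` when given, else the library RT); otherwise the
    height is zero and the peak counts as not detected. Absence of signal
    is a value, not an error.
    """
    mz = theoretical_mz(entry.formula, entry.ion, iso_k)
    mz_win = ppm_window(mz, params.tol_ppm)
    rt_win = (entry.rt_min - params.rt_search_min, entry.rt_min + params.rt_search_min)
    trace = xic(run, mz_win, rt_win, entry.ion.polarity, combine=params.centroid_combine)
    reference = consensus_apex_rt if consensus_apex_rt is not None else entry.rt_min
    best_rt: float | None = None
    best_int = 0.0
    for rt, inten in trace:
        if inten > best_int or (
            inten == best_int
            and inten > 0
            and best_rt is not None
            and abs(rt - reference) < abs(best_rt - reference)
        ):
            best_rt, best_int = rt, inten
    if best_rt is None or best_int <= 0:
        return PeakMeasurement(entry.name, run.sample_id, None, 0.0, False)
    if abs(best_rt - reference) > params.apex_tol_min:
        return PeakMeasurement(entry.name, run.sample_id, None, 0.0, False)
    return PeakMeasurement(entry.name, run.sample_id, best_rt, best_int, True)


def consensus_apex(measurements: Sequence[PeakMeasurement]) -> float | None:
    """Median apex RT over measurements with nonzero height; None if none."""
    apexes = [m.apex_rt for m in measurements if m.height > 0 and m.apex_rt is not None]
    if not apexes:
        return None
    return float(np.median(apexes))


@dataclass
class IntensityMatrix:
    """Metabolites x samples peak-height table plus sample metadata.

    heights : DataFrame, index = metabolite names, columns = sample ids
        (study samples and blanks).
    samples : DataFrame indexed by sample id with 'group' and 'role'
        columns (role in {study, blank}).
    detail : long-form per-peak table (metabolite, sample, apex_rt_min,
        height, detected_raw).
    """

    heights: pd.DataFrame
    samples: pd.DataFrame
    detail: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.heights.to_numpy() < 0).any():
            raise ValueError("intensity matrix must be non-negative")
        missing = [c for c in self.heights.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples table missing entries for: {missing}")

    @property
    def study_columns(self) -> list[str]:
        return [c for c in self.heights.columns if self.samples.loc[c, "role"] == "study"]

    @property
    def blank_columns(self) -> list[str]:
        return [c for c in self.heights.columns if self.samples.loc[c, "role"] == "blank"]

    def to_tsv(self, path: str | Path) -> None:
        self.heights.rename_axis("metabolite").to_csv(path, sep="\t")


def build_matrix(
    runs: Sequence[SampleRun],
    library: Sequence[MetaboliteLibraryEntry],
    params: ExtractionParams = ExtractionParams(),
) -> IntensityMatrix:
    """Extract every library entry from every run into an intensity matrix.

    Two passes by default: pass 1 extracts each study sample against the
    library RT and takes the per-metabolite median apex (the consensus);
    pass 2 re-extracts every run (including blanks) against that consensus.
    Blanks never vote on the consensus.
    """
    ids = [r.sample_id for r in runs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample id(s): {dupes}")
    study_runs = [r for r in runs if r.role == "study"]

    references: dict[str, float | None] = {e.name: None for e in library}
    if params.consensus:
        for entry in library:
            pass1 = [extract_peak(r, entry, params) for r in study_runs]
            references[entry.name] = consensus_apex(pass1)

    records = []
    heights = np.zeros((len(library), len(runs)))
    for i, entry in enumerate(library):
        ref = references[entry.name]
        for j, run in enumerate(runs):
            m = extract_peak(run, entry, params, consensus_apex_rt=ref)
            heights[i, j] = m.height
            records.append(
                {
                    "metabolite": m.metabolite,
                    "sample": m.sample_id,
                    "apex_rt_min": m.apex_rt,
                    "height": m.height,
                    "detected_raw": m.detected_raw,
                }
            )
    heights_df = pd.DataFrame(heights, index=[e.name for e in library], columns=ids)
    samples_df = pd.DataFrame(
        {"group": [r.group for r in runs], "role": [r.role for r in runs]}, index=pd.Index(ids, name="sample_id")
    )
    return IntensityMatrix(heights_df, samples_df, pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# File-based inputs


def read_library(path: str | Path) -> list[MetaboliteLibraryEntry]:
    """Read a metabolite library TSV: name, formula (Hill), ion_type, rt_min."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "formula", "ion_type", "rt_min"}
    if not required.issubset(df.columns):
        raise ValueError(f"library table must have columns {sorted(required)}, got {list(df.columns)}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            MetaboliteLibraryEntry(
                name=str(row.name),
                formula=ElementalFormula.parse(str(row.formula)),
                ion=get_ion_type(str(row.ion_type)),
                rt_min=float(row.rt_min),
            )
        )
    return entries


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, group, role (study|blank)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}, got {list(df.columns)}")
    bad = sorted(set(df["role"]) - {"study", "blank"})
    if bad:
        raise ValueError(f"sample roles must be 'study' or 'blank', got {bad}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample id(s): {dupes}")
    return df.set_index("sample_id")


def load_runs(mzml_dir: str | Path, samples: pd.DataFrame) -> list[SampleRun]:
    """Load all ``<sample_id>.mzML`` files named in the sample sheet."""
    runs = []
    for sample_id, row in samples.iterrows():
        path = Path(mzml_dir) / f"{sample_id}.mzML"
        if not path.exists():
            raise FileNotFoundError(f"no mzML file for sample {sample_id!r}: {path}")
        spectra = _mzml.read_spectra(path)
        runs.append(SampleRun(str(sample_id), str(row["role"]), str(row["group"]), spectra))
    return runs
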