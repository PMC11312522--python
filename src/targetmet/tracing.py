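"""Natural-abundance correction and enrichment for 13C tracing data.

For a metabolite with n carbons measured as isotopologue intensities
m+0 ... m+n, the correction removes the signal expected from naturally
occurring 13C so that what remains reflects tracer incorporation. The
default rule is the m+0-anchored subtraction:

    corrected[k] = max(0, raw[k] - C(n,k) * (a/(1-a))^k * raw[0]),  k >= 1
    corrected[0] = raw[0]

where a is the natural 13C abundance (0.0107 by default) and
C(n,k) * (a/(1-a))^k is the binomial probability of a purely unlabeled
molecule appearing at m+k, expressed relative to m+0. This subtracts only
the natural contribution anchored at the monoisotopic pool and does not
cascade the natural envelopes of labeled species; an optional
matrix-inversion mode ('matrix') performs the full cascade for
comparison. Only carbon is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom

from .chem import ElementalFormula
from .extraction import (
    ExtractionParams,
    MetaboliteLibraryEntry,
    SampleRun,
    consensus_apex,
    extract_peak,
)

__all__ = [
    "NaturalAbundanceModel",
    "IsotopologueSeries",
    "natural_fraction_ratio",
    "natural_envelope",
    "correct_series",
    "enrichment",
    "trace_matrix",
]


@dataclass(frozen=True)
class NaturalAbundanceModel:
    """Binomial natural-abundance model for one element (carbon)."""

    n_carbons: int
    heavy_fraction: float = 0.0107

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError("carbon count must be >= 1")
        if not 0 < self.heavy_fraction < 1:
            raise ValueError("heavy-isotope fraction must be in (0, 1)")


@dataclass
class IsotopologueSeries:
    """Raw and corrected m+0..m+n intensities for one metabolite/sample."""

    metabolite: str
    formula: ElementalFormula
    sample_id: str
    raw: np.ndarray
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 1:
            raise ValueError("raw intensities must be one-dimensional")
        if (self.raw < 0).any():
            raise ValueError("raw intensities must be >= 0")
        n_c = self.formula.carbon_count
        if len(self.raw) != n_c + 1:
            raise ValueError(
                f"series for {self.metabolite!r} has {len(self.raw)} entries, expected {n_c + 1} (m+0..m+{n_c})"
            )


def natural_fraction_ratio(model: NaturalAbundanceModel, k: int) -> float:
    """Natural probability of m+k relative to m+0: C(n,k) * (a/(1-a))^k."""
    if not 0 <= k <= model.n_carbons:
        raise ValueError(f"isotopologue index k={k} out of range 0..{model.n_carbons}")
    a = model.heavy_fraction
    return comb(model.n_carbons, k) * (a / (1.0 - a)) ** k


def natural_envelope(model: NaturalAbundanceModel) -> np.ndarray:
    """Binomial isotopologue probabilities for k = 0..n (sums to 1)."""
    k = np.arange(model.n_carbons + 1)
    return _binom.pmf(k, model.n_carbons, model.heavy_fraction)


def correct_series(
    series: IsotopologueSeries,
    model: NaturalAbundanceModel | None = None,
    mode: str = "subtract",
) -> IsotopologueSeries:
    """Natural-abundance-correct one series; m+0 passes through unchanged,
    negatives are clamped to zero.

    mode 'subtract' (default) removes only the m+0-anchored natural
    contribution; mode 'matrix' inverts the full binomial mixing matrix
    (each labeled pool m+j contributes its own natural envelope to
    heavier isotopologues) before clamping.
    """
    n_c = series.formula.carbon_count
    if model is None:
        model = NaturalAbundanceModel(n_carbons=n_c)
    if model.n_carbons != n_c:
        raise ValueError(f"model carbon count {model.n_carbons} != formula carbon count {n_c}")
    raw = series.raw
    if mode == "subtract":
        corrected = raw.copy()
        for k in range(1, n_c + 1):
            corrected[k] = max(0.0, raw[k] - natural_fraction_ratio(model, k) * raw[0])
    elif mode == "matrix":
        # M[j, k] = P(labeled pool at k observed at j) for j >= k
        a = model.heavy_fraction
        size = n_c + 1
        mix = np.zeros((size, size))
        for k in range(size):
            j = np.arange(k, size)
            mix[j, k] = _binom.pmf(j - k, n_c - k, a)
        pools = np.linalg.solve(mix, raw)
        corrected = np.clip(pools, 0.0, None)
        corrected[0] = raw[0]
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    return IsotopologueSeries(series.metabolite, series.formula, series.sample_id, raw, corrected)


def enrichment(series: IsotopologueSeries) -> np.ndarray | None:
    """Fractional labeling per k from the corrected envelope; fractions sum
    to 1. None (flagged absent) when the corrected total is zero."""
    if series.corrected is None:
        raise ValueError("series must be corrected before computing enrichment")
    total = float(series.corrected.sum())
    if total <= 0:
        return None
    return series.corrected / total


def trace_matrix(
    runs: Sequence[SampleRun],
    library: Sequence[MetaboliteLibraryEntry],
    params: ExtractionParams = ExtractionParams(),
    model_abundance: float = 0.0107,
    mode: str = "subtract",
) -> pd.DataFrame:
    """Extract m+0..m+n per (metabolite, sample), correct, and summarize.

    The m+0 peak is extracted with the two-pass consensus scheme across
    study samples; heavier isotopologues co-elute, so each k >= 1 is
    extracted against the same consensus apex. Returns a long table with
    columns metabolite, sample, k, raw, corrected, fraction.
    """
    ids = [r.sample_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    study_runs = [r for r in runs if r.role == "study"]
    rows = []
    for entry in library:
        n_c = entry.formula.carbon_count
        if n_c < 1:
            continue
        reference = None
        if params.consensus and study_runs:
            pass1 = [extract_peak(r, entry, params) for r in study_runs]
            reference = consensus_apex(pass1)
        model = NaturalAbundanceModel(n_carbons=n_c, heavy_fraction=model_abundance)
        for run in runs:
            raw = np.array(
                [
                    extract_peak(run, entry, params, consensus_apex_rt=reference, iso_k=k).height
                    for k in range(n_c + 1)
                ]
            )
            series = IsotopologueSeries(entry.name, entry.formula, run.sample_id, raw)
            series = correct_series(series, model, mode=mode)
            fractions = enrichment(series)
            for k in range(n_c + 1):
                rows.append(
                    {
                        "metabolite": entry.name,
                        "sample": run.sample_id,
                        "k": k,
                        "raw": series.raw[k],
                        "corrected": series.corrected[k],
                        "fraction": float(fractions[k]) if fractions is not None else np.nan,
                    }
                )
    return pd.DataFrame.from_records(rows)
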