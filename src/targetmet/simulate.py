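"""Ground-truthed synthetic LC-MS runs emulating a targeted HILIC workflow.

The generator emits what the downstream stages consume: polarity-switching
centroid MS1 runs over a 42-minute gradient, Gaussian elution profiles at
library retention times with ppm-scale mass error, low-level baseline
centroids, blank runs carrying a small fraction of study signal, and
binomial isotopologue envelopes for tracing experiments. Every quantity
is stored as ground truth alongside the simulated output, and all
randomness descends from a single seed.

Two layers exist on purpose. ``simulate_truth`` draws the true peak
heights, retention times and differential effects as plain tables without
materializing any spectra — this is what matrix-level statistical checks
use, and it scales to thousands of metabolites. ``simulate_experiment``
materializes centroid spectra from the same truth (identical under the
same seed) for the mzML-level extraction checks.

Reference retention times are aligned to the acquisition grid of the
metabolite's polarity, so in the zero-jitter limit the chromatographic
apex is sampled exactly and extraction recovers true heights bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _mzml
from .chem import ElementalFormula, get_ion_type, theoretical_mz
from .extraction import MetaboliteLibraryEntry, SampleRun, Spectrum
from .tracing import IsotopologueSeries, NaturalAbundanceModel, natural_envelope

__all__ = [
    "BUILTIN_COMPOUNDS",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_library",
    "simulate_truth",
    "simulate_run",
    "simulate_experiment",
    "simulate_isotopologue_series",
    "write_experiment",
]

# Real small-molecule formulas with the adduct each is typically observed
# under in a polarity-switching ZIC-pHILIC method.
BUILTIN_COMPOUNDS: list[tuple[str, str, str]] = [
    ("glucose", "C6H12O6", "[M-H]-"),
    ("lactate", "C3H6O3", "[M-H]-"),
    ("pyruvate", "C3H4O3", "[M-H]-"),
    ("citrate", "C6H8O7", "[M-H]-"),
    ("alpha-ketoglutarate", "C5H6O5", "[M-H]-"),
    ("succinate", "C4H6O4", "[M-H]-"),
    ("fumarate", "C4H4O4", "[M-H]-"),
    ("malate", "C4H6O5", "[M-H]-"),
    ("orotate", "C5H4N2O4", "[M-H]-"),
    ("creatine", "C4H9N3O2", "[M+H]+"),
    ("creatinine", "C4H7N3O", "[M+H]+"),
    ("pantothenate", "C9H17NO5", "[M-H]-"),
    ("taurine", "C2H7NO3S", "[M-H]-"),
    ("hypotaurine", "C2H7NO2S", "[M+H]+"),
    ("glutathione", "C10H17N3O6S", "[M+H]+"),
    ("glycine", "C2H5NO2", "[M+H]+"),
    ("alanine", "C3H7NO2", "[M+H]+"),
    ("serine", "C3H7NO3", "[M+H]+"),
    ("proline", "C5H9NO2", "[M+H]+"),
    ("valine", "C5H11NO2", "[M+H]+"),
    ("threonine", "C4H9NO3", "[M+H]+"),
    ("cysteine", "C3H7NO2S", "[M+H]+"),
    ("leucine", "C6H13NO2", "[M+H]+"),
    ("asparagine", "C4H8N2O3", "[M+H]+"),
    ("aspartate", "C4H7NO4", "[M-H]-"),
    ("glutamine", "C5H10N2O3", "[M+H]+"),
    ("glutamate", "C5H9NO4", "[M-H]-"),
    ("lysine", "C6H14N2O2", "[M+H]+"),
    ("methionine", "C5H11NO2S", "[M+H]+"),
    ("histidine", "C6H9N3O2", "[M+H]+"),
    ("phenylalanine", "C9H11NO2", "[M+H]+"),
    ("arginine", "C6H14N4O2", "[M+H]+"),
    ("tryptophan", "C11H12N2O2", "[M+H]+"),
    ("tyrosine", "C9H11NO3", "[M+H]+"),
    ("uridine", "C9H12N2O6", "[M-H]-"),
    ("hypoxanthine", "C5H4N4O", "[M+H]+"),
]


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.

    Units: retention times in minutes, scan interval and widths in
    seconds, intensities in arbitrary units (a.u.). ``seed`` fixes all
    randomness end to end.
    """

    seed: int = 0
    n_metabolites: int = 20
    n_samples_per_group: int = 6
    groups: tuple[str, ...] = ("control", "treated")
    n_blanks: int = 3
    rt_range: tuple[float, float] = (0.0, 42.0)
    #: seconds between consecutive MS1 scans; polarity alternates scan to
    #: scan, so each polarity is revisited every 2 x scan_interval_s.
    scan_interval_s: float = 1.0
    mass_error_ppm_sd: float = 2.0
    rt_jitter_sd_s: float = 2.0
    #: Gaussian sigma of the elution profile (FWHM ~ 2.35 sigma).
    peak_sigma_s: float = 8.0
    baseline_level: float = 1000.0
    baseline_centroids_per_scan: float = 2.0
    #: multiplicative between-sample coefficient of variation.
    sample_cv: float = 0.20
    #: blank signal as a fraction of the mean study intensity.
    blank_carryover: float = 0.01
    base_intensity_range: tuple[float, float] = (1e5, 5e6)
    #: metabolite name -> log2 fold change of non-reference groups vs groups[0].
    true_log2fc: dict[str, float] = field(default_factory=dict)
    #: metabolite name -> {k: fraction} of tracer-labeled isotopologues;
    #: requires isotope_envelopes=True to affect the emitted spectra.
    labeled_fractions: dict[str, dict[int, float]] | None = None
    isotope_envelopes: bool = False
    natural_abundance: float = 0.0107
    detect_floor_reference: float = 10000.0

    def __post_init__(self) -> None:
        if self.n_metabolites < 1 or self.n_samples_per_group < 1 or self.n_blanks < 0:
            raise ValueError("counts must be >= 1 (blanks >= 0)")
        if len(self.groups) < 1:
            raise ValueError("at least one group required")
        for name, val in (
            ("mass_error_ppm_sd", self.mass_error_ppm_sd),
            ("rt_jitter_sd_s", self.rt_jitter_sd_s),
            ("sample_cv", self.sample_cv),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.peak_sigma_s <= 0 or self.scan_interval_s <= 0:
            raise ValueError("peak_sigma_s and scan_interval_s must be positive")


@dataclass
class GroundTruth:
    """True quantities behind a simulated experiment.

    heights : true apex heights, metabolites x all samples (blanks carry
        the carryover level). apex_rt : true apex retention time in
        minutes per cell. log2fc : true per-metabolite effect (0 = null).
    labeled_fractions : tracer ground truth when isotope envelopes are on.
    """

    heights: pd.DataFrame
    apex_rt: pd.DataFrame
    log2fc: pd.Series
    labeled_fractions: dict[str, dict[int, float]] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metabolite_order": list(self.heights.index),
            "sample_order": list(self.heights.columns),
            "heights": {m: self.heights.loc[m].to_dict() for m in self.heights.index},
            "apex_rt": {m: self.apex_rt.loc[m].to_dict() for m in self.apex_rt.index},
            "log2fc": self.log2fc.to_dict(),
            "labeled_fractions": (
                {m: {str(k): v for k, v in d.items()} for m, d in self.labeled_fractions.items()}
                if self.labeled_fractions
                else None
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        mets = payload["metabolite_order"]
        cols = payload["sample_order"]
        heights = pd.DataFrame(payload["heights"]).T.loc[mets, cols]
        apex = pd.DataFrame(payload["apex_rt"]).T.loc[mets, cols]
        lf = payload.get("labeled_fractions")
        return cls(
            heights=heights,
            apex_rt=apex,
            log2fc=pd.Series(payload["log2fc"]),
            labeled_fractions=(
                {m: {int(k): v for k, v in d.items()} for m, d in lf.items()} if lf else None
            ),
        )


@dataclass
class SimulatedExperiment:
    library: list[MetaboliteLibraryEntry]
    samples: pd.DataFrame  # indexed by sample_id: group, role
    runs: list[SampleRun]
    truth: GroundTruth
    config: SimulationConfig


def _scan_grid(config: SimulationConfig) -> tuple[np.ndarray, float]:
    """Scan start times in seconds and the scan interval."""
    t0 = config.rt_range[0] * 60.0
    t1 = config.rt_range[1] * 60.0
    n = int(np.floor((t1 - t0) / config.scan_interval_s)) + 1
    return t0 + np.arange(n) * config.scan_interval_s, config.scan_interval_s

def _snap_to_grid(rt_min: float, polarity: str, config: SimulationConfig) -> float:
    """Nearest scan time (minutes) of the given polarity; '+' scans sit on
    even grid indices, '-' on odd ones."""
    times, delta = _scan_grid(config)
    want_even = polarity == "+"
    idx = int(round((rt_min * 60.0 - times[0]) / delta))
    if (idx % 2 == 0) != want_even:
        idx += 1 if idx + 1 < len(times) else -1
    idx = min(max(idx, 0 if want_even else 1), len(times) - 1)
    if (idx % 2 == 0) != want_even:
        idx -= 1
    return float(times[idx] / 60.0)


def simulate_library(config: SimulationConfig) -> list[MetaboliteLibraryEntry]:
    """Deterministic targeted library: real formulas, grid-aligned RTs.

    Formulas cycle through the built-in compound set when
    ``n_metabolites`` exceeds it (names get a numeric suffix); reference
    RTs are spread evenly across the interior of ``rt_range``.
    """
    n = config.n_metabolites
    lo, hi = config.rt_range
    span = hi - lo
    rts = np.linspace(lo + 0.08 * span, hi - 0.08 * span, n)
    entries = []
    m = len(BUILTIN_COMPOUNDS)
    for i in range(n):
        name, formula, ion_label = BUILTIN_COMPOUNDS[i % m]
        if i >= m:
            name = f"{name}_{i // m + 1}"
        ion = get_ion_type(ion_label)
        rt = _snap_to_grid(float(rts[i]), ion.polarity, config)
        entries.append(MetaboliteLibraryEntry(name, ElementalFormula.parse(formula), ion, rt))
    return entries


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for g in config.groups:
        for i in range(config.n_samples_per_group):
            rows.append((f"{g}_{i + 1}", g, "study"))
    for i in range(config.n_blanks):
        rows.append((f"blank_{i + 1}", "blank", "blank"))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "role"])
    return df.set_index("sample_id")


def _truth_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])


def simulate_truth(
    config: SimulationConfig, library: Sequence[MetaboliteLibraryEntry] | None = None
) -> tuple[list[MetaboliteLibraryEntry], pd.DataFrame, GroundTruth]:
    """Draw ground-truth heights, apex RTs and effects (no spectra).

    Group means differ by ``true_log2fc`` on the log2 scale; samples get
    mean-preserving multiplicative lognormal noise at ``sample_cv``;
    blanks carry ``blank_carryover`` x the mean study intensity.
    """
    library = list(library) if library is not None else simulate_library(config)
    samples = _sample_sheet(config)
    rng = _truth_rng(config)
    names = [e.name for e in library]
    n_met = len(names)

    lo, hi = np.log10(config.base_intensity_range[0]), np.log10(config.base_intensity_range[1])
    base = 10.0 ** rng.uniform(lo, hi, n_met)
    fc = pd.Series([config.true_log2fc.get(nm, 0.0) for nm in names], index=names, dtype=float)

    study_ids = [s for s in samples.index if samples.loc[s, "role"] == "study"]
    blank_ids = [s for s in samples.index if samples.loc[s, "role"] == "blank"]
    group_of = samples["group"]

    sigma = float(np.sqrt(np.log1p(config.sample_cv**2)))
    heights = pd.DataFrame(0.0, index=names, columns=list(samples.index))
    means = np.empty((n_met, len(study_ids)))
    for j, sid in enumerate(study_ids):
        g = group_of[sid]
        effect = np.where(g == config.groups[0], 0.0, fc.to_numpy())
        means[:, j] = base * np.exp2(effect)
    noise = np.exp(rng.standard_normal((n_met, len(study_ids))) * sigma - sigma**2 / 2.0) if sigma > 0 else 1.0
    heights.loc[:, study_ids] = means * noise

    if blank_ids:
        blank_mean = config.blank_carryover * heights[study_ids].mean(axis=1).to_numpy()
        bnoise = (
            np.exp(rng.standard_normal((n_met, len(blank_ids))) * sigma - sigma**2 / 2.0)
            if sigma > 0
            else 1.0
        )
        heights.loc[:, blank_ids] = blank_mean[:, None] * bnoise

    lib_rt = np.array([e.rt_min for e in library])
    jitter = (
        rng.standard_normal((n_met, len(samples.index))) * config.rt_jitter_sd_s / 60.0
        if config.rt_jitter_sd_s > 0
        else np.zeros((n_met, len(samples.index)))
    )
    apex = pd.DataFrame(lib_rt[:, None] + jitter, index=names, columns=list(samples.index))

    truth = GroundTruth(heights, apex, fc, labeled_fractions=config.labeled_fractions)
    return library, samples, truth


def _envelopes(
    library: Sequence[MetaboliteLibraryEntry], config: SimulationConfig
) -> dict[str, np.ndarray]:
    """Per-metabolite isotopologue intensity shares (index k), m+0-only
    when envelopes are off."""
    out: dict[str, np.ndarray] = {}
    labeled = config.labeled_fractions or {}
    for entry in library:
        n_c = entry.formula.carbon_count
        if not config.isotope_envelopes:
            out[entry.name] = np.array([1.0])
            continue
        model = NaturalAbundanceModel(n_carbons=max(n_c, 1), heavy_fraction=config.natural_abundance)
        nat = natural_envelope(model) if n_c >= 1 else np.array([1.0])
        shares = dict(labeled.get(entry.name, {}))
        total_labeled = sum(shares.values())
        if total_labeled > 1 + 1e-12:
            raise ValueError(f"labeled fractions for {entry.name} sum to {total_labeled} > 1")
        env = (1.0 - total_labeled) * nat
        for k, frac in shares.items():
            if not 0 <= k <= n_c:
                raise ValueError(f"labeled isotopologue k={k} out of range for {entry.name}")
            env[k] += frac
        out[entry.name] = env
    return out


def simulate_run(
    library: Sequence[MetaboliteLibraryEntry],
    truth: GroundTruth,
    config: SimulationConfig,
    sample_id: str,
    role: str,
    group: str,
    rng: np.random.Generator,
) -> SampleRun:
    """Materialize one acquisition: alternating-polarity centroid MS1 scans
    with Gaussian elution profiles at the truth heights plus baseline."""
    times_s, delta = _scan_grid(config)
    n_scans = len(times_s)
    scan_mz: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    scan_int: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    envelopes = _envelopes(library, config)

    for entry in library:
        height = float(truth.heights.loc[entry.name, sample_id])
        if height <= 0:
            continue
        apex_s = float(truth.apex_rt.loc[entry.name, sample_id]) * 60.0
        sigma = config.peak_sigma_s
        want_even = entry.ion.polarity == "+"
        i_lo = max(int(np.ceil((apex_s - 6 * sigma - times_s[0]) / delta)), 0)
        i_hi = min(int(np.floor((apex_s + 6 * sigma - times_s[0]) / delta)), n_scans - 1)
        if i_hi < i_lo:
            continue
        idx = np.arange(i_lo, i_hi + 1)
        idx = idx[(idx % 2 == 0) == want_even]
        if len(idx) == 0:
            continue
        t = times_s[idx]
        profile = np.exp(-((t - apex_s) ** 2) / (2.0 * sigma**2))
        for k, share in enumerate(envelopes[entry.name]):
            if share <= 0:
                continue
            mz0 = theoretical_mz(entry.formula, entry.ion, k)
            eps = (
                rng.standard_normal(len(idx)) * config.mass_error_ppm_sd
                if config.mass_error_ppm_sd > 0
                else np.zeros(len(idx))
            )
            mzvals = mz0 * (1.0 + eps * 1e-6)
            intvals = height * share * profile
            for pos, i_scan in enumerate(idx):
                scan_mz[i_scan].append(mzvals[pos : pos + 1])
                scan_int[i_scan].append(intvals[pos : pos + 1])

    if config.baseline_level > 0 and config.baseline_centroids_per_scan > 0:
        counts = rng.poisson(config.baseline_centroids_per_scan, n_scans)
        total = int(counts.sum())
        noise_mz = rng.uniform(67.0, 1000.0, total)
        noise_int = rng.exponential(config.baseline_level, total)
        offset = 0
        for i_scan in range(n_scans):
            c = counts[i_scan]
            if c:
                scan_mz[i_scan].append(noise_mz[offset : offset + c])
                scan_int[i_scan].append(noise_int[offset : offset + c])
                offset += c

    spectra = []
    for i_scan in range(n_scans):
        polarity = "+" if i_scan % 2 == 0 else "-"
        if scan_mz[i_scan]:
            mz = np.concatenate(scan_mz[i_scan])
            inten = np.concatenate(scan_int[i_scan])
        else:
            mz = np.empty(0)
            inten = np.empty(0)
        spectra.append(Spectrum(rt=times_s[i_scan] / 60.0, polarity=polarity, mz=mz, intensity=inten))
    return SampleRun(sample_id, role, group, spectra)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Simulate the full study: all study samples, all blanks, plus truth."""
    library, samples, truth = simulate_truth(config)
    children = np.random.SeedSequence(config.seed).spawn(1 + len(samples))
    runs = []
    for i, (sid, row) in enumerate(samples.iterrows()):
        rng = np.random.default_rng(children[1 + i])
        runs.append(simulate_run(library, truth, config, sid, row["role"], row["group"], rng))
    return SimulatedExperiment(library, samples, runs, truth, config)


def simulate_isotopologue_series(
    formula: ElementalFormula | str,
    labeled_fraction_by_k: Mapping[int, float],
    total_intensity: float,
    natural_abundance: float = 0.0107,
    seed: int | None = None,
    noise_cv: float = 0.0,
    metabolite: str = "",
    sample_id: str = "",
) -> IsotopologueSeries:
    """One raw isotopologue envelope: unlabeled share at the binomial
    natural-abundance envelope plus tracer-labeled shares at their k,
    optionally with multiplicative noise of the given CV."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    n_c = formula.carbon_count
    if n_c < 1:
        raise ValueError("isotopologue series require at least one carbon")
    if total_intensity < 0:
        raise ValueError("total intensity must be >= 0")
    shares = dict(labeled_fraction_by_k)
    if any(v < 0 for v in shares.values()):
        raise ValueError("labeled fractions must be >= 0")
    labeled_total = sum(shares.values())
    if labeled_total > 1 + 1e-12:
        raise ValueError(f"labeled fractions sum to {labeled_total} > 1")
    model = NaturalAbundanceModel(n_carbons=n_c, heavy_fraction=natural_abundance)
    env = (1.0 - labeled_total) * natural_envelope(model)
    for k, frac in shares.items():
        if not 0 <= k <= n_c:
            raise ValueError(f"labeled isotopologue k={k} out of range 0..{n_c}")
        env[k] += frac
    raw = total_intensity * env
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        raw = raw * np.exp(rng.standard_normal(len(raw)) * sigma - sigma**2 / 2.0)
    return IsotopologueSeries(
        metabolite=metabolite or str(formula),
        formula=formula,
        sample_id=sample_id,
        raw=raw,
    )


def write_experiment(experiment: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write runs as mzML plus library.tsv, samples.tsv, ground_truth.json."""
    outdir = Path(outdir)
    mzml_dir = outdir / "mzml"
    mzml_dir.mkdir(parents=True, exist_ok=True)
    for run in experiment.runs:
        _mzml.write_mzml(run, mzml_dir / f"{run.sample_id}.mzML")
    lib_path = outdir / "library.tsv"
    pd.DataFrame(
        {
            "name": [e.name for e in experiment.library],
            "formula": [str(e.formula) for e in experiment.library],
            "ion_type": [e.ion.label for e in experiment.library],
            "rt_min": [repr(float(e.rt_min)) for e in experiment.library],
        }
    ).to_csv(lib_path, sep="\t", index=False)
    samples_path = outdir / "samples.tsv"
    experiment.samples.reset_index().to_csv(samples_path, sep="\t", index=False)
    truth_path = outdir / "ground_truth.json"
    experiment.truth.to_json(truth_path)
    return {"mzml_dir": mzml_dir, "library": lib_path, "samples": samples_path, "truth": truth_path}
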