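"""Ground-truthed DOM-like spectrum simulation.

The generator emulates the statistical structure of a negative-mode
ESI FT-ICR MS spectrum of dissolved organic matter well enough that
every pipeline stage has a recoverable target:

* a library of hundreds to thousands of CHNOS formulas drawn inside the
  assignment constraint box (C 1-90, H 4-200, O 1-26, N 0-2, S 0-1),
  with integer DBE >= 0 and [M-H]- m/z inside the working window;
* log-normal signal intensities over a separate, lower log-normal noise
  population (separated by construction so the log-intensity noise-mode
  estimator has a target);
* a smooth quadratic m/z-dependent relative mass error (ppm), the model
  class the internal calibration fits;
* blank spectra sharing a contaminant subset of the library with the
  samples, enabling the same-day blank-subtraction rule.

What it does NOT emulate: isotope clusters, peak shape, space-charge
effects, chemically realistic intensity covariance between formulas.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_core import MolecularFormula, default_mass_table, ion_mz
from .spectra_io import PeakList, SampleMetadata


class GenerationError(ValueError):
    """Raised when a simulation config cannot be satisfied."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic DOM spectrum generator.

    Intensities are in arbitrary detector units; ``intensity_lognormal``
    and ``noise_lognormal`` are (mu, sigma) of the natural-log intensity.
    ``drift_coeffs`` (a0, a1, a2) inject a relative mass error
    ``e(m) = a0 + a1*m + a2*m**2`` in ppm, applied multiplicatively:
    observed = true * (1 + e(true)/1e6).
    """

    seed: int
    n_formulas: int = 500
    mz_range: tuple[float, float] = (100.0, 700.0)
    cho_fraction: float = 0.7
    chno_fraction: float = 0.2
    chnos_fraction: float = 0.1
    intensity_lognormal: tuple[float, float] = (6.0, 1.0)
    noise_peaks: int = 1000
    noise_lognormal: tuple[float, float] = (2.0, 0.3)
    drift_coeffs: tuple[float, float, float] = (0.1, 1e-3, 1e-6)
    blank_overlap_fraction: float = 0.05
    # constraint box the library is sampled from
    c_range: tuple[int, int] = (1, 90)
    h_range: tuple[int, int] = (4, 200)
    o_range: tuple[int, int] = (1, 26)
    n_range: tuple[int, int] = (0, 2)
    s_range: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        fr = (self.cho_fraction, self.chno_fraction, self.chnos_fraction)
        if any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise GenerationError("composition fractions must lie in [0,1] and sum to 1")
        if not self.mz_range[0] < self.mz_range[1]:
            raise GenerationError("mz_range low must be below high")
        if self.n_formulas <= 0:
            raise GenerationError("n_formulas must be positive")
        if not 0.0 <= self.blank_overlap_fraction <= 1.0:
            raise GenerationError("blank_overlap_fraction must lie in [0,1]")


@dataclass
class GroundTruth:
    """Per-peak provenance of a simulated spectrum.

    ``df`` columns: observed_mz, true_mz, true_formula (Hill string, empty
    for noise), intensity, is_noise.
    """

    df: pd.DataFrame

    def formulas(self) -> set[MolecularFormula]:
        return {MolecularFormula.from_hill(f)
                for f in self.df.loc[~self.df["is_noise"], "true_formula"]}

    def write(self, path) -> None:
        self.df.to_csv(path, index=False)


def _drift_ppm(coeffs: Sequence[float], mz: np.ndarray) -> np.ndarray:
    a0, a1, a2 = coeffs
    return a0 + a1 * mz + a2 * mz**2


def generate_formula_library(config: SimulationConfig) -> list[MolecularFormula]:
    """Sample ``n_formulas`` distinct, chemically valid CHNOS formulas.

    Composition type (CHO / CHNO / CHNOS) is drawn per the configured mix;
    C, O and DBE are sampled in DOM-plausible ranges and H follows from
    DBE, which guarantees integer DBE >= 0 and the right H parity.
    Formulas whose [M-H]- m/z falls outside ``mz_range`` are rejected.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    table = default_mass_table()
    lo, hi = config.mz_range
    c_hi = min(config.c_range[1], int(hi / 12) + 1)
    library: set[MolecularFormula] = set()
    max_draws = 2000 * config.n_formulas
    stall_window = 20_000  # draws without a new formula => box is exhausted
    since_new = 0
    for _ in range(max_draws):
        if since_new >= stall_window:
            break
        since_new += 1
        u = rng.random()
        if u < config.cho_fraction:
            n_atoms, s_atoms = 0, 0
        elif u < config.cho_fraction + config.chno_fraction:
            n_atoms, s_atoms = int(rng.integers(1, config.n_range[1] + 1)), 0
        else:
            n_atoms = int(rng.integers(1, config.n_range[1] + 1))
            s_atoms = 1
        c = int(rng.integers(4, c_hi + 1))
        o = int(rng.integers(config.o_range[0], min(config.o_range[1], c) + 1))
        d = int(rng.integers(0, min(15, c) + 1))
        h = 2 + 2 * c + n_atoms - 2 * d  # from DBE = 1 + C - H/2 + N/2
        if not (config.h_range[0] <= h <= config.h_range[1]):
            continue
        f = MolecularFormula(c=c, h=h, n=n_atoms, o=o, s=s_atoms)
        if not (lo <= ion_mz(f, table) <= hi):
            continue
        if f not in library:
            library.add(f)
            since_new = 0
        if len(library) >= config.n_formulas:
            break
    if len(library) < config.n_formulas:
        raise GenerationError(
            f"could only generate {len(library)}/{config.n_formulas} formulas; "
            "constraint box too small for the requested library size")
    return sorted(library, key=lambda f: ion_mz(f, table))


def _emit_spectrum(
    formulas: Sequence[MolecularFormula],
    config: SimulationConfig,
    rng: np.random.Generator,
    meta: SampleMetadata,
    n_noise: int,
) -> tuple[PeakList, GroundTruth]:
    table = default_mass_table()
    true_mz = np.array([ion_mz(f, table) for f in formulas])
    observed = true_mz * (1.0 + _drift_ppm(config.drift_coeffs, true_mz) / 1e6)
    mu, sigma = config.intensity_lognormal
    intens = np.exp(rng.normal(mu, sigma, size=len(formulas)))

    n_mu, n_sigma = config.noise_lognormal
    noise_mz = rng.uniform(config.mz_range[0], config.mz_range[1], size=n_noise)
    noise_int = np.exp(rng.normal(n_mu, n_sigma, size=n_noise))

    truth = pd.DataFrame({
        "observed_mz": np.concatenate([observed, noise_mz]),
        "true_mz": np.concatenate([true_mz, np.full(n_noise, np.nan)]),
        "true_formula": [f.hill() for f in formulas] + [""] * n_noise,
        "intensity": np.concatenate([intens, noise_int]),
        "is_noise": [False] * len(formulas) + [True] * n_noise,
    }).sort_values("observed_mz").reset_index(drop=True)

    df = pd.DataFrame({"mz": truth["observed_mz"], "intensity": truth["intensity"]})
    return PeakList(df=df, meta=meta), GroundTruth(df=truth)


def simulate_sample(
    library: Sequence[MolecularFormula],
    config: SimulationConfig,
    meta: SampleMetadata | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PeakList, GroundTruth]:
    """Emit one sample spectrum: library signal plus noise peaks."""
    if len(library) == 0:
        raise GenerationError("cannot simulate from an empty library")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    meta = meta or SampleMetadata(sample_id="synthetic-sample")
    return _emit_spectrum(list(library), config, rng, meta, config.noise_peaks)


def blank_contaminants(
    library: Sequence[MolecularFormula], config: SimulationConfig
) -> list[MolecularFormula]:
    """The designated contaminant subset shared between blanks and samples.

    Deterministic for a given library and config: a seeded choice of
    ``blank_overlap_fraction`` of the library.
    """
    k = int(round(config.blank_overlap_fraction * len(library)))
    rng = np.random.default_rng(config.seed + 7919)  # independent of sample draws
    idx = rng.choice(len(library), size=k, replace=False)
    return [library[i] for i in sorted(idx)]


def simulate_blank(
    library: Sequence[MolecularFormula],
    config: SimulationConfig,
    meta: SampleMetadata | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PeakList, GroundTruth]:
    """Emit a methanol-blank spectrum: contaminant formulas plus noise."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    meta = meta or SampleMetadata(sample_id="synthetic-blank", sample_type="blank")
    if meta.sample_type != "blank":
        meta = dataclasses.replace(meta, sample_type="blank")
    contaminants = blank_contaminants(library, config)
    return _emit_spectrum(contaminants, config, rng, meta, config.noise_peaks)


def simulate_bulk_ea(
    formula_mixture: Sequence[tuple[MolecularFormula, float]],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    organic_fraction: float = 1.0,
) -> dict[str, float]:
    """Bulk elemental-analysis weight-% of a formula mixture.

    Mole fractions must sum to 1.  Weight percentages use standard atomic
    weights (an elemental analyzer burns natural-isotope material), with
    additive Gaussian noise of ``noise_sd`` wt-% clipped at 0.  Returns
    keys ``wt_c, wt_h, wt_n, wt_o, wt_c_org``.
    """
    fracs = np.array([x for _, f in formula_mixture for x in [f]], dtype=float)
    if len(fracs) == 0 or abs(fracs.sum() - 1.0) > 1e-9:
        raise GenerationError("mole fractions must sum to 1")
    w = default_mass_table().atomic_weight
    mass = {el: 0.0 for el in ("C", "H", "N", "O")}
    for formula, frac in formula_mixture:
        mass["C"] += frac * formula.c * w["C"]
        mass["H"] += frac * formula.h * w["H"]
        mass["N"] += frac * formula.n * w["N"]
        mass["O"] += frac * formula.o * w["O"]
    # sulfur contributes to total mass but is not reported by the EA record
    total = sum(mass.values()) + sum(
        frac * formula.s * w["S"] for formula, frac in formula_mixture)
    rng = rng if rng is not None else np.random.default_rng(0)
    out = {}
    for el in ("C", "H", "N", "O"):
        pct = 100.0 * mass[el] / total
        if noise_sd > 0:
            pct += rng.normal(0.0, noise_sd)
        out[f"wt_{el.lower()}"] = max(pct, 0.0)
    out["wt_c_org"] = out["wt_c"] * organic_fraction
    return out


# --------------------------------------------------------------------------
# Whole-dataset emission (the `simulate` CLI subcommand's engine)
# --------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    library: list[MolecularFormula]
    samples: list[tuple[PeakList, GroundTruth]]
    blanks: list[tuple[PeakList, GroundTruth]]
    manifest: list[SampleMetadata] = field(default_factory=list)


def simulate_dataset(
    config: SimulationConfig,
    n_samples: int = 3,
    sites: Sequence[str] = ("headwater", "reservoir"),
    start_month: int = 1,
    year: int = 2019,
) -> SimulatedDataset:
    """Simulate a small monthly campaign: paired-site samples plus one
    same-day blank per acquisition date.

    Sample ``i`` is collected at ``sites[i % len(sites)]`` in month
    ``start_month + i // len(sites)``; each distinct acquisition date gets
    one blank, so every sample has a same-day blank.
    """
    library = generate_formula_library(config)
    rng = np.random.default_rng(config.seed + 1)
    samples, blanks, manifest = [], [], []
    seen_dates = set()
    for i in range(n_samples):
        site = sites[i % len(sites)]
        month = (start_month - 1 + i // len(sites)) % 12 + 1
        date = _dt.date(year, month, 15)
        meta = SampleMetadata(
            sample_id=f"{site}-{year}-{month:02d}", site_id=site,
            collection_date=date, sample_type="sample", acquisition_date=date)
        samples.append(simulate_sample(library, config, meta, rng))
        manifest.append(meta)
        if date not in seen_dates:
            seen_dates.add(date)
            bmeta = SampleMetadata(
                sample_id=f"blank-{year}-{month:02d}", site_id="",
                collection_date=date, sample_type="blank", acquisition_date=date)
            blanks.append(simulate_blank(library, config, bmeta, rng))
            manifest.append(bmeta)
    return SimulatedDataset(library=library, samples=samples, blanks=blanks,
                            manifest=manifest)
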