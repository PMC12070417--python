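"""Internal mass recalibration against a CHO homologous series.

Natural organic matter spectra contain an abundant backbone of CHO-only
formulas at low DBE; their theoretical [M-H]- masses serve as internal
calibrants.  The procedure:

1. enumerate the CHO reference series inside the working m/z window
   (default DBE set {0, 1}; DBE -1 is impossible for a neutral CHO
   molecule and such entries are accepted in config but logged as
   unreachable),
2. match observed peaks to reference masses (nearest neighbor within a
   ppm tolerance, greedy one-to-one by ascending |error|),
3. least-squares fit a degree-2 polynomial of relative error (ppm)
   against the matched references' theoretical m/z — error is modeled in
   ppm because FT-ICR mass error scales with m/z,
4. divide every observed m/z by (1 + e(m)/1e6).

Fitting against theoretical rather than observed m/z makes drift that is
polynomial in true m/z exactly recoverable; evaluating the fitted model
at observed m/z during correction perturbs the prediction only at
O(ppm^2), far below the sub-ppm tolerances in play.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .chem_core import MolecularFormula, default_mass_table, ion_mz
from .spectra_io import PeakList

logger = logging.getLogger("fticrdom")

DEFAULT_DBE_SET = frozenset({-1, 0, 1})
DEFAULT_MATCH_TOL_PPM = 1.0
MIN_MATCHES = 3


class CalibrationError(ValueError):
    """Empty reference series, too few matches, or a degenerate fit."""


@dataclass(frozen=True)
class ReferenceSeries:
    """CHO-only calibrant formulas and their theoretical [M-H]- masses."""

    formulas: tuple[MolecularFormula, ...]
    ion_mzs: np.ndarray  # sorted ascending, parallel to formulas

    def __len__(self) -> int:
        return len(self.formulas)


@dataclass(frozen=True)
class CalibrationModel:
    """Quadratic model of relative mass error (ppm) as a function of m/z."""

    coeffs: tuple[float, float, float]
    n_matched: int
    rms_ppm_before: float
    rms_ppm_after: float

    def predict_ppm(self, mz) -> np.ndarray:
        a0, a1, a2 = self.coeffs
        mz = np.asarray(mz, dtype=float)
        return a0 + a1 * mz + a2 * mz**2

    def correct(self, mz) -> np.ndarray:
        """Remove the modeled relative error from observed m/z values."""
        mz = np.asarray(mz, dtype=float)
        return mz / (1.0 + self.predict_ppm(mz) / 1e6)


def build_reference_series(
    mz_low: float,
    mz_high: float,
    dbe_set: frozenset[int] | set[int] = DEFAULT_DBE_SET,
    c_range: tuple[int, int] = (1, 90),
    h_range: tuple[int, int] = (4, 200),
    o_range: tuple[int, int] = (1, 26),
) -> ReferenceSeries:
    """Enumerate all CHO formulas in the box with DBE in ``dbe_set`` and
    ion m/z inside [mz_low, mz_high], sorted by m/z."""
    if not dbe_set:
        raise CalibrationError("dbe_set must not be empty")
    feasible = sorted(d for d in dbe_set if d >= 0)
    skipped = sorted(set(dbe_set) - set(feasible))
    if skipped:
        logger.info("reference DBE value(s) %s unreachable for neutral CHO "
                    "formulas; using %s", skipped, feasible)
    if not feasible:
        raise CalibrationError("no feasible DBE values in dbe_set")
    table = default_mass_table()
    entries = []
    for d in feasible:
        for c in range(c_range[0], c_range[1] + 1):
            h = 2 + 2 * c - 2 * d  # DBE = 1 + C - H/2
            if not (h_range[0] <= h <= h_range[1]):
                continue
            for o in range(o_range[0], o_range[1] + 1):
                f = MolecularFormula(c=c, h=h, o=o)
                mz = ion_mz(f, table)
                if mz_low <= mz <= mz_high:
                    entries.append((mz, f))
    if not entries:
        raise CalibrationError("reference series is empty for this window")
    entries.sort(key=lambda t: t[0])
    return ReferenceSeries(
        formulas=tuple(f for _, f in entries),
        ion_mzs=np.array([m for m, _ in entries]),
    )


def match_references(
    peaks: PeakList,
    series: ReferenceSeries,
    match_tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
) -> list[tuple[float, float]]:
    """One-to-one (observed, theoretical) pairs within the ppm tolerance.

    Candidate pairs are every (peak, reference) within tolerance; they are
    accepted greedily by ascending |ppm error| with each peak and each
    reference used at most once.
    """
    if match_tol_ppm <= 0:
        raise ValueError("match_tol_ppm must be positive")
    obs = peaks.mz
    candidates = []
    for j, theo in enumerate(series.ion_mzs):
        tol_da = match_tol_ppm * 1e-6 * theo
        i0, i1 = np.searchsorted(obs, [theo - tol_da, theo + tol_da])
        for i in range(i0, i1):
            err_ppm = (obs[i] - theo) / theo * 1e6
            candidates.append((abs(err_ppm), i, j))
    candidates.sort()
    used_peaks: set[int] = set()
    used_refs: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_peaks or j in used_refs:
            continue
        used_peaks.add(i)
        used_refs.add(j)
        pairs.append((float(obs[i]), float(series.ion_mzs[j])))
    if len(pairs) < MIN_MATCHES:
        raise CalibrationError(
            f"only {len(pairs)} reference match(es); need >= {MIN_MATCHES}")
    pairs.sort(key=lambda t: t[1])
    return pairs


def _rms(values: np.ndarray) -> float:
    return float(math.sqrt(np.mean(np.square(values))))


def fit_error_model(pairs, degree: int = 2) -> CalibrationModel:
    """Least-squares polynomial fit of ppm error vs theoretical m/z."""
    obs = np.array([p[0] for p in pairs])
    theo = np.array([p[1] for p in pairs])
    if len(pairs) < degree + 1:
        raise CalibrationError(f"{len(pairs)} pair(s) cannot constrain degree {degree}")
    if np.ptp(theo) == 0:
        raise CalibrationError("all matches at one m/z: rank-deficient fit")
    err_ppm = (obs - theo) / theo * 1e6
    rms_before = _rms(err_ppm)
    # fit in a scaled domain for conditioning, then convert to plain coeffs
    poly = np.polynomial.Polynomial.fit(theo, err_ppm, deg=degree).convert()
    coeffs = list(poly.coef) + [0.0] * (3 - len(poly.coef))
    model = CalibrationModel(coeffs=tuple(coeffs[:3]), n_matched=len(pairs),
                             rms_ppm_before=rms_before, rms_ppm_after=math.nan)
    corrected = model.correct(obs)
    rms_after = _rms((corrected - theo) / theo * 1e6)
    if rms_after > rms_before:
        # second-order effects can in principle undo a near-zero improvement;
        # fall back to the identity model so correction never degrades
        logger.warning("calibration fit did not improve RMS; using identity model")
        return CalibrationModel(coeffs=(0.0, 0.0, 0.0), n_matched=len(pairs),
                                rms_ppm_before=rms_before, rms_ppm_after=rms_before)
    return CalibrationModel(coeffs=model.coeffs, n_matched=len(pairs),
                            rms_ppm_before=rms_before, rms_ppm_after=rms_after)


def apply_calibration(peaks: PeakList, model: CalibrationModel) -> PeakList:
    """Attach a ``calibrated_mz`` column; raw m/z and intensities untouched."""
    df = peaks.df.copy()
    df["calibrated_mz"] = model.correct(df["mz"].to_numpy())
    return peaks.with_df(df)


def calibrate(
    peaks: PeakList,
    mz_low: float,
    mz_high: float,
    dbe_set=DEFAULT_DBE_SET,
    match_tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
    degree: int = 2,
) -> tuple[PeakList, CalibrationModel]:
    """Convenience wrapper: build series, match, fit, apply."""
    series = build_reference_series(mz_low, mz_high, dbe_set)
    pairs = match_references(peaks, series, match_tol_ppm)
    model = fit_error_model(pairs, degree=degree)
    return apply_calibration(peaks, model), model


def plot_error_model(pairs, model: CalibrationModel, path) -> None:
    """Diagnostic scatter of ppm error vs m/z with the fitted polynomial.

    The same inspection the match tolerance is predetermined from.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = np.array([p[0] for p in pairs])
    theo = np.array([p[1] for p in pairs])
    err = (obs - theo) / theo * 1e6
    grid = np.linspace(theo.min(), theo.max(), 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(theo, err, s=8, alpha=0.6, label="matched references")
    ax.plot(grid, model.predict_ppm(grid), color="C1", label="fitted error model")
    ax.set_xlabel("m/z (Th)")
    ax.set_ylabel("mass error (ppm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
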