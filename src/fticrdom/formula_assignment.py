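"""Constrained CHNOS molecular-formula assignment and blank subtraction.

Each peak's (calibrated) m/z is matched against every neutral formula in
the constraint box — default C 1-90, H 4-200, O 1-26, N 0-2, S 0-1 —
whose [M-H]- ion mass falls within a ppm tolerance (default +/-0.5 ppm).
The enumeration iterates the (N, S, O, C) sub-grid and solves the
residual mass for the hydrogen count in closed form, which is exactly
equivalent to brute force over the box (the test suite asserts this
against an exhaustive enumeration) but runs in ~10^4 rather than ~10^6
operations per peak.

Ambiguity is resolved by a deterministic, configurable tie-break:
smallest |ppm error|, then fewest heteroatoms (N+S), then lowest DBE,
with the Hill string as a final total-order tie-break.

Blank subtraction removes from each sample any formula detected in a
same-day methanol blank at a blank-relative prominence strictly above a
threshold (default 20% of the blank's base peak).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_core import MolecularFormula, dbe, default_mass_table, ion_mz
from .spectra_io import AssignedPeak, AssignedSample, PeakList

logger = logging.getLogger("fticrdom")

TIE_BREAK_KEYS = ("abs_ppm", "heteroatoms", "dbe")


@dataclass(frozen=True)
class AssignmentConfig:
    """Element-count bounds, mass tolerance and tie-break policy."""

    c_range: tuple[int, int] = (1, 90)
    h_range: tuple[int, int] = (4, 200)
    o_range: tuple[int, int] = (1, 26)
    n_range: tuple[int, int] = (0, 2)
    s_range: tuple[int, int] = (0, 1)
    tol_ppm: float = 0.5
    require_integer_dbe_ge_zero: bool = True
    tie_break_order: tuple[str, ...] = TIE_BREAK_KEYS
    include_electron: bool = True

    def __post_init__(self) -> None:
        for name in ("c_range", "h_range", "o_range", "n_range", "s_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} is empty or negative: ({lo}, {hi})")
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        unknown = set(self.tie_break_order) - set(TIE_BREAK_KEYS)
        if unknown:
            raise ValueError(f"unknown tie-break key(s): {sorted(unknown)}")


@dataclass(frozen=True)
class Candidate:
    """One formula within tolerance of a peak, with its signed error."""

    formula: MolecularFormula
    ppm_error: float


@dataclass(frozen=True)
class BlankPolicy:
    """Same-day blank-subtraction rule (strict > threshold)."""

    prominence_pct_threshold: float = 20.0
    same_day_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.prominence_pct_threshold <= 100.0:
            raise ValueError("prominence threshold must lie in (0, 100]")


class _CandidateGrid:
    """Precomputed (n, s, o, c) base masses for fast hydrogen solving."""

    def __init__(self, config: AssignmentConfig):
        table = default_mass_table()
        m = table.monoisotopic
        ns, ss, os_, cs = np.meshgrid(
            np.arange(config.n_range[0], config.n_range[1] + 1),
            np.arange(config.s_range[0], config.s_range[1] + 1),
            np.arange(config.o_range[0], config.o_range[1] + 1),
            np.arange(config.c_range[0], config.c_range[1] + 1),
            indexing="ij",
        )
        self.n = ns.ravel()
        self.s = ss.ravel()
        self.o = os_.ravel()
        self.c = cs.ravel()
        self.base_mass = (self.c * m["C"] + self.n * m["N"]
                          + self.o * m["O"] + self.s * m["S"])
        self.m_h = m["H"]
        self.proton_shift = m["H"] - (table.electron if config.include_electron else 0.0)


_GRID_CACHE: dict[tuple, _CandidateGrid] = {}


def _grid_for(config: AssignmentConfig) -> _CandidateGrid:
    key = (config.c_range, config.h_range, config.o_range, config.n_range,
           config.s_range, config.include_electron)
    if key not in _GRID_CACHE:
        _GRID_CACHE[key] = _CandidateGrid(config)
    return _GRID_CACHE[key]


def enumerate_candidates(mz: float, config: AssignmentConfig) -> list[Candidate]:
    """All box formulas whose [M-H]- mass lies within ``tol_ppm`` of ``mz``.

    Complete and deterministic: equal to the brute-force sweep of the full
    constraint box.  An empty list is a legal result.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    grid = _grid_for(config)
    tol = config.tol_ppm * 1e-6
    # neutral-mass window covering every theoretical mass with
    # |mz - theo|/theo <= tol, padded by 1 nDa against rounding; exact
    # membership is re-checked in ppm below
    m_lo = mz / (1.0 + tol) + grid.proton_shift - 1e-9
    m_hi = mz / (1.0 - tol) + grid.proton_shift + 1e-9

    h_min = np.ceil((m_lo - grid.base_mass) / grid.m_h).astype(np.int64)
    h_max = np.floor((m_hi - grid.base_mass) / grid.m_h).astype(np.int64)
    h_min = np.maximum(h_min, config.h_range[0])
    h_max = np.minimum(h_max, config.h_range[1])
    hits = np.nonzero(h_max >= h_min)[0]

    out: list[Candidate] = []
    for i in hits:
        c, n, o, s = int(grid.c[i]), int(grid.n[i]), int(grid.o[i]), int(grid.s[i])
        for h in range(int(h_min[i]), int(h_max[i]) + 1):
            f = MolecularFormula(c=c, h=h, n=n, o=o, s=s)
            if config.require_integer_dbe_ge_zero:
                d = dbe(f)
                if d < 0 or d != int(d):
                    continue
            theo = ion_mz(f, include_electron=config.include_electron)
            err = (mz - theo) / theo * 1e6
            if abs(err) <= config.tol_ppm:
                out.append(Candidate(formula=f, ppm_error=err))
    out.sort(key=lambda cand: _tie_break_key(cand, config.tie_break_order))
    return out


def _tie_break_key(cand: Candidate, order: tuple[str, ...]):
    parts = []
    for rule in order:
        if rule == "abs_ppm":
            parts.append(abs(cand.ppm_error))
        elif rule == "heteroatoms":
            parts.append(cand.formula.heteroatoms)
        elif rule == "dbe":
            parts.append(dbe(cand.formula))
    parts.append(cand.formula.hill())  # total order
    return tuple(parts)


def assign_peaklist(peaks: PeakList, config: AssignmentConfig | None = None) -> AssignedSample:
    """Assign every peak its best candidate; unassigned peaks retained."""
    config = config or AssignmentConfig()
    mz_obs = peaks.mz
    mz_eff = peaks.effective_mz
    intensity = peaks.intensity
    out = []
    for raw, eff, inten in zip(mz_obs, mz_eff, intensity):
        cands = enumerate_candidates(float(eff), config)
        if cands:
            best = cands[0]
            out.append(AssignedPeak(mz=float(raw), intensity=float(inten),
                                    calibrated_mz=float(eff), formula=best.formula,
                                    ppm_error=best.ppm_error, n_candidates=len(cands)))
        else:
            out.append(AssignedPeak(mz=float(raw), intensity=float(inten),
                                    calibrated_mz=float(eff)))
    n_assigned = sum(p.assigned for p in out)
    logger.info("%s: assigned %d/%d peaks", peaks.meta.sample_id, n_assigned, len(out))
    return AssignedSample(meta=peaks.meta, peaks=out)


# --------------------------------------------------------------------------
# Blank subtraction
# --------------------------------------------------------------------------


def blank_formula_prominences(blank: AssignedSample) -> dict[MolecularFormula, float]:
    """Percent prominence of each assigned blank formula relative to the
    blank's own base peak (most intense peak, assigned or not)."""
    base = blank.base_peak_intensity
    if base <= 0:
        return {}
    prom: dict[MolecularFormula, float] = {}
    for p in blank.assigned_peaks:
        pct = p.intensity / base * 100.0
        prom[p.formula] = max(pct, prom.get(p.formula, 0.0))
    return prom


def blank_subtract(
    samples: list[AssignedSample],
    blanks: list[AssignedSample],
    policy: BlankPolicy | None = None,
) -> tuple[list[AssignedSample], pd.DataFrame]:
    """Remove same-day blank contaminants above the prominence threshold.

    Returns the filtered samples and a removal log with columns
    ``sample_id, formula, blank_id, blank_prominence_pct``.  A sample with
    no same-day blank passes through unchanged (with a warning).
    """
    policy = policy or BlankPolicy()
    log_rows = []
    filtered: list[AssignedSample] = []
    for sample in samples:
        relevant = [
            b for b in blanks
            if not policy.same_day_only
            or (b.meta.acquisition_date is not None
                and b.meta.acquisition_date == sample.meta.acquisition_date)
        ]
        if policy.same_day_only and not relevant:
            logger.warning("%s: no same-day blank; sample unchanged",
                           sample.meta.sample_id)
            filtered.append(sample)
            continue
        to_remove: dict[MolecularFormula, tuple[str, float]] = {}
        for blank in relevant:
            for formula, pct in blank_formula_prominences(blank).items():
                if pct > policy.prominence_pct_threshold:
                    prev = to_remove.get(formula)
                    if prev is None or pct > prev[1]:
                        to_remove[formula] = (blank.meta.sample_id, pct)
        kept = []
        for p in sample.peaks:
            if p.assigned and p.formula in to_remove:
                blank_id, pct = to_remove[p.formula]
                log_rows.append((sample.meta.sample_id, p.formula.hill(),
                                 blank_id, pct))
                continue
            kept.append(p)
        filtered.append(AssignedSample(meta=sample.meta, peaks=kept))
    log = pd.DataFrame(
        log_rows, columns=["sample_id", "formula", "blank_id", "blank_prominence_pct"])
    if len(log):
        logger.info("blank subtraction removed %d peak(s) across %d sample(s)",
                    len(log), log["sample_id"].nunique())
    return filtered, log
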