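"""Shared fixtures: the exhaustive formula-enumeration oracle and small
synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from fticrdom.chem_core import default_mass_table
from fticrdom.synthetic_data import SimulationConfig, generate_formula_library


class BruteForceBox:
    """Exhaustive sweep of the CHNOS constraint box.

    Independent of the package's pruned enumeration: every (c, h, n, o, s)
    quintuple in the box is materialized once with vectorized arithmetic
    and queried by binary search on sorted ion mass.  This is the oracle
    the fast enumerator is checked against.
    """

    C_RANGE = (1, 90)
    H_RANGE = (4, 200)
    O_RANGE = (1, 26)
    N_RANGE = (0, 2)
    S_RANGE = (0, 1)

    def __init__(self) -> None:
        t = default_mass_table()
        m = t.monoisotopic
        c = np.arange(self.C_RANGE[0], self.C_RANGE[1] + 1)
        h = np.arange(self.H_RANGE[0], self.H_RANGE[1] + 1)
        n = np.arange(self.N_RANGE[0], self.N_RANGE[1] + 1)
        o = np.arange(self.O_RANGE[0], self.O_RANGE[1] + 1)
        s = np.arange(self.S_RANGE[0], self.S_RANGE[1] + 1)
        C, H, N, O, S = np.meshgrid(c, h, n, o, s, indexing="ij")
        self.c = C.ravel().astype(np.int16)
        self.h = H.ravel().astype(np.int16)
        self.n = N.ravel().astype(np.int16)
        self.o = O.ravel().astype(np.int16)
        self.s = S.ravel().astype(np.int16)
        ion = (self.c * m["C"] + self.h * m["H"] + self.n * m["N"]
               + self.o * m["O"] + self.s * m["S"]) - m["H"] + t.electron
        order = np.argsort(ion, kind="stable")
        self.ion = ion[order]
        for name in ("c", "h", "n", "o", "s"):
            setattr(self, name, getattr(self, name)[order])
        self.dbe = 1.0 + self.c - self.h / 2.0 + self.n / 2.0
        self.dbe_ok = (self.dbe >= 0) & (self.dbe == np.floor(self.dbe))

    def candidates(self, mz: float, tol_ppm: float,
                   require_integer_dbe_ge_zero: bool = True) -> set[tuple]:
        """All (c, h, n, o, s) with |mz - ion|/ion * 1e6 <= tol_ppm."""
        tol = tol_ppm * 1e-6
        lo = np.searchsorted(self.ion, mz / (1.0 + tol) - 1e-7)
        hi = np.searchsorted(self.ion, mz / (1.0 - tol) + 1e-7)
        out = set()
        for i in range(lo, hi):
            err = (mz - self.ion[i]) / self.ion[i] * 1e6
            if abs(err) > tol_ppm:
                continue
            if require_integer_dbe_ge_zero and not self.dbe_ok[i]:
                continue
            out.add((int(self.c[i]), int(self.h[i]), int(self.n[i]),
                     int(self.o[i]), int(self.s[i])))
        return out


@pytest.fixture(scope="session")
def brute_force_box() -> BruteForceBox:
    return BruteForceBox()


@pytest.fixture(scope="session")
def small_library():
    """A 150-formula library under the default study-condition mix."""
    return generate_formula_library(SimulationConfig(seed=11, n_formulas=150))


@pytest.fixture(scope="session")
def default_sim_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_formulas=150)
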