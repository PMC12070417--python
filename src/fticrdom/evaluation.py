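"""Scoring pipeline output against simulation ground truth.

Only meaningful for synthetic datasets, where every peak's true formula
(or noise status) is on record.  Peaks are joined on m/z rounded to the
6 decimal places of the peak-list CSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class RecoveryScore:
    """Assignment quality of one sample against its ground truth.

    ``n_truth`` counts distinct true formulas emitted in the spectrum;
    ``n_recovered`` those correctly assigned in the output (a formula
    removed by blank subtraction counts as recovered when listed in
    ``removed_formulas`` — removal is deliberate, not a miss);
    ``n_false`` assigned peaks whose formula does not match their truth
    (noise peaks assigned anything, signal peaks assigned wrongly).
    """

    n_truth: int
    n_recovered: int
    n_assigned: int
    n_false: int

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.n_recovered / self.n_truth if self.n_truth else 0.0

    @property
    def false_pct(self) -> float:
        return 100.0 * self.n_false / self.n_assigned if self.n_assigned else 0.0


def _truth_map(truth_df: pd.DataFrame) -> dict[float, str]:
    out: dict[float, str] = {}
    for row in truth_df.itertuples(index=False):
        formula = "" if row.is_noise else row.true_formula
        out[round(float(row.observed_mz), 6)] = formula
    return out


def score_assignments(
    assignments: pd.DataFrame,
    truth_df: pd.DataFrame,
    removed_formulas: set[str] = frozenset(),
) -> RecoveryScore:
    """Score an assignments table (the CSV layout) against a ground-truth
    table (columns observed_mz, true_formula, is_noise)."""
    truth = _truth_map(truth_df)
    true_formulas = {f for f in truth.values() if f}
    correct: set[str] = set()
    n_assigned = 0
    n_false = 0
    for row in assignments.itertuples(index=False):
        formula = row.formula if isinstance(row.formula, str) else ""
        if not formula:
            continue
        n_assigned += 1
        expected = truth.get(round(float(row.mz), 6), "")
        if formula == expected:
            correct.add(formula)
        else:
            n_false += 1
    recovered = correct | (true_formulas & set(removed_formulas))
    return RecoveryScore(
        n_truth=len(true_formulas),
        n_recovered=len(recovered & true_formulas),
        n_assigned=n_assigned,
        n_false=n_false,
    )


def score_pipeline_output(
    out_dir: str | Path,
    sim_dir: str | Path,
    sample_id: str,
) -> RecoveryScore:
    """Score one sample of a ``run_pipeline`` output tree against the
    ground truth emitted next to the simulated peak lists."""
    out_dir, sim_dir = Path(out_dir), Path(sim_dir)
    assignments = pd.read_csv(out_dir / f"assignments_{sample_id}.csv",
                              comment="#", keep_default_na=False)
    truth_df = pd.read_csv(sim_dir / f"{sample_id}.truth.csv",
                           keep_default_na=False)
    truth_df["is_noise"] = truth_df["is_noise"].astype(bool)
    removals = pd.read_csv(out_dir / "blank_removals.csv")
    removed = set(removals.loc[removals["sample_id"] == sample_id, "formula"])
    return score_assignments(assignments, truth_df, removed)
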