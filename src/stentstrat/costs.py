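"""Per-patient cost model: initial treatment costs, corrective-procedure
costs for adverse events, baseline-workflow costs, savings, and the stent-cost
sensitivity grid.

Monetary constants are configuration. Stent procedure costs default to the
midpoints of the +/-25% sensitivity ranges anchored at reimbursement rates
($11,866 BMS, $12,456 DES — their difference is the published $590 gap);
bypass surgery defaults to $28,683. Costs of dual anti-platelet therapy,
myocardial infarction, stroke and corrective procedures have no published
default here and must be supplied; ``placeholder_cost_table`` ships clearly
labelled synthetic values for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .effectiveness import EffectivenessEstimates


@dataclass(frozen=True)
class CostTable:
    """Per-patient costs in USD. c_dapt/c_mi/c_stroke/c_corrective are
    required configuration (no published default)."""

    c_dapt: float
    c_mi: float
    c_stroke: float
    c_corrective: float
    c_sbms: float = 11866.0
    c_sdes: float = 12456.0
    c_cabg: float = 28683.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "CostTable":
        """Load from YAML or JSON config with the field names above."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


def placeholder_cost_table() -> CostTable:
    """Synthetic placeholder values for the four config-required costs, for
    testing only: round-number magnitudes plausible for US reimbursements,
    not published figures."""
    return CostTable(c_dapt=1300.0, c_mi=20000.0, c_stroke=15000.0, c_corrective=15000.0)


@dataclass
class CostEstimates:
    initial_proposed: float
    corrective_proposed: float
    initial_baseline: float
    corrective_baseline: float

    @property
    def total_proposed(self) -> float:
        return self.initial_proposed + self.corrective_proposed

    @property
    def total_baseline(self) -> float:
        return self.initial_baseline + self.corrective_baseline

    @property
    def total_savings(self) -> float:
        return self.total_baseline - self.total_proposed

    @property
    def savings_pct(self) -> float:
        return 100.0 * self.total_savings / self.total_baseline


def proposed_initial_cost(p_sbms: float, p_sdes: float, p_scabg: float, costs: CostTable) -> float:
    """Expected initial cost of the suggested treatments: stent arms carry a
    year of dual anti-platelet therapy, the surgical arm does not."""
    if abs(p_sbms + p_sdes + p_scabg - 1.0) > 1e-9:
        raise ValueError("treatment probabilities must sum to 1")
    return (
        p_sbms * (costs.c_sbms + costs.c_dapt)
        + p_sdes * (costs.c_sdes + costs.c_dapt)
        + p_scabg * costs.c_cabg
    )


def adverse_event_cost(p_hazard: float, p_restenosis: float, costs: CostTable) -> float:
    """Expected corrective cost: hazardous events incur half MI + half stroke
    treatment plus a corrective procedure; restenosis a corrective procedure."""
    for name, v in (("p_hazard", p_hazard), ("p_restenosis", p_restenosis)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return (
        p_hazard * (0.5 * (costs.c_mi + costs.c_stroke) + costs.c_corrective)
        + p_restenosis * costs.c_corrective
    )


def baseline_costs(
    omega: float, costs: CostTable, baseline: EffectivenessEstimates
) -> tuple[float, float]:
    """Initial and corrective per-patient costs of the predominant-DES
    baseline with grey-zone fraction omega split half DES / half CABG."""
    if not 0 <= omega <= 1:
        raise ValueError(f"omega must be in [0, 1], got {omega}")
    initial = (1 - omega) * (costs.c_sdes + costs.c_dapt) + 0.5 * omega * (
        costs.c_cabg + costs.c_sdes + costs.c_dapt
    )
    corrective = adverse_event_cost(baseline.p_hazard, baseline.p_restenosis, costs)
    return initial, corrective


def cost_report(
    proposed: EffectivenessEstimates,
    baseline: EffectivenessEstimates,
    three_vessel_rate: float,
    costs: CostTable,
    lambda_grey: float = 0.21,
) -> CostEstimates:
    """Full cost comparison of the proposed cascade against the baseline."""
    omega = lambda_grey * three_vessel_rate
    initial_b, corrective_b = baseline_costs(omega, costs, baseline)
    initial_p = proposed_initial_cost(proposed.p_sbms, proposed.p_sdes, proposed.p_scabg, costs)
    corrective_p = adverse_event_cost(proposed.p_hazard, proposed.p_restenosis, costs)
    return CostEstimates(
        initial_proposed=initial_p,
        corrective_proposed=corrective_p,
        initial_baseline=initial_b,
        corrective_baseline=corrective_b,
    )


def cost_report_frame(estimates: CostEstimates) -> "pd.DataFrame":
    """Cost comparison as a report table (one row per cost line)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"quantity": "Initial costs (Baseline)", "value": estimates.initial_baseline},
            {"quantity": "Initial costs (Proposed)", "value": estimates.initial_proposed},
            {"quantity": "Corrective procedure (Baseline)", "value": estimates.corrective_baseline},
            {"quantity": "Corrective procedure (Proposed)", "value": estimates.corrective_proposed},
            {"quantity": "Total savings", "value": estimates.total_savings},
            {"quantity": "Total savings (%)", "value": estimates.savings_pct},
        ]
    )


def sensitivity_grid(
    proposed: EffectivenessEstimates,
    baseline: EffectivenessEstimates,
    three_vessel_rate: float,
    costs: CostTable,
    lambda_grey: float = 0.21,
    span: float = 0.25,
    step: float = 0.0125,
) -> dict:
    """Total savings over a grid of stent procedure costs varied +/-span in
    steps of ``step`` (41 x 41 points at the defaults), all other inputs fixed.

    Returns axes (rounded to whole dollars for reporting) and the savings
    matrix with BMS cost varying along rows, DES cost along columns.
    """
    n = int(round(2 * span / step)) + 1
    factors = 1.0 + np.linspace(-span, span, n)
    bms_axis = costs.c_sbms * factors
    des_axis = costs.c_sdes * factors
    savings = np.empty((n, n))
    for i, cb in enumerate(bms_axis):
        for j, cd in enumerate(des_axis):
            ct = CostTable(
                c_dapt=costs.c_dapt,
                c_mi=costs.c_mi,
                c_stroke=costs.c_stroke,
                c_corrective=costs.c_corrective,
                c_sbms=float(cb),
                c_sdes=float(cd),
                c_cabg=costs.c_cabg,
            )
            savings[i, j] = cost_report(proposed, baseline, three_vessel_rate, ct, lambda_grey).total_savings
    return {
        "bms_axis": np.round(bms_axis).astype(int),
        "des_axis": np.round(des_axis).astype(int),
        "savings": savings,
    }
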