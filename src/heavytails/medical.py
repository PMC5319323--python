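"""Conversion of two-arm binomial outcomes to differences of proportions.

Ratio-style endpoints (e.g. mortality rate on drug vs placebo) are not
Normal, so each trial's intervention/control event counts are converted to a
*difference* of proportions, which is asymptotically Normal when ``n``,
``np`` and ``n(1-p)`` are all large.  The asymmetric uncertainty of the
difference comes from central exact (Clopper-Pearson) 68.3% binomial
confidence intervals on each arm, combined side-wise in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats

from .core import MeasurementRecord

__all__ = [
    "CI68_LEVEL",
    "TwoArmCounts",
    "binomial_ci68",
    "to_difference",
    "gaussian_limit_check",
    "read_two_arm_counts",
    "write_two_arm_counts",
]

#: Nominal two-sided coverage matching one Normal standard deviation.
CI68_LEVEL = 0.683


@dataclass(frozen=True)
class TwoArmCounts:
    """Event counts of one two-arm trial (intervention and control)."""

    n_int: int
    k_int: int
    n_ctrl: int
    k_ctrl: int
    study_id: str = ""
    quantity_id: str = ""
    year: float | None = None

    def __post_init__(self) -> None:
        for n, k, arm in ((self.n_int, self.k_int, "intervention"),
                          (self.n_ctrl, self.k_ctrl, "control")):
            if n < 1:
                raise ValueError(f"{arm} arm of {self.study_id}: n must be >= 1")
            if not 0 <= k <= n:
                raise ValueError(f"{arm} arm of {self.study_id}: need 0 <= k <= n")

    def swapped(self) -> "TwoArmCounts":
        return TwoArmCounts(self.n_ctrl, self.k_ctrl, self.n_int, self.k_int,
                            self.study_id, self.quantity_id, self.year)


def binomial_ci68(k: int, n: int) -> tuple[float, float, float]:
    """Central exact 68.3% binomial interval; returns ``(p_hat, lo, hi)``.

    Clopper-Pearson tail inversion, so the interval is well defined at the
    ``k=0`` (lo = 0) and ``k=n`` (hi = 1) boundaries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=CI68_LEVEL,
                                             method="exact")
    return k / n, float(ci.low), float(ci.high)


def to_difference(arms: TwoArmCounts) -> MeasurementRecord:
    """Convert two-arm counts to a difference of proportions.

    value = p_int - p_ctrl.  The plus-side uncertainty combines the upper CI
    half-width of the intervention arm with the lower half-width of the
    control arm in quadrature (a fluctuation up in the difference means
    intervention up or control down); the minus side combines the opposite
    halves.  Bounds are the trivial [-1, 1] range of a difference of
    fractions.
    """
    p_i, lo_i, hi_i = binomial_ci68(arms.k_int, arms.n_int)
    p_c, lo_c, hi_c = binomial_ci68(arms.k_ctrl, arms.n_ctrl)
    u_plus = math.hypot(hi_i - p_i, p_c - lo_c)
    u_minus = math.hypot(p_i - lo_i, hi_c - p_c)
    return MeasurementRecord(
        quantity_id=arms.quantity_id or arms.study_id or "diff",
        value=p_i - p_c,
        u_plus=u_plus,
        u_minus=u_minus,
        year=arms.year,
        lower_bound=-1.0,
        upper_bound=1.0,
        record_id=arms.study_id or None,
    )


def read_two_arm_counts(path: str | Path) -> list[TwoArmCounts]:
    """Read trial tables from CSV: study_id,quantity_id,n_int,k_int,n_ctrl,k_ctrl,year."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(TwoArmCounts(
            n_int=int(row["n_int"]), k_int=int(row["k_int"]),
            n_ctrl=int(row["n_ctrl"]), k_ctrl=int(row["k_ctrl"]),
            study_id=str(row.get("study_id", "")),
            quantity_id=str(row.get("quantity_id", "")),
            year=float(row["year"]) if "year" in row and pd.notna(row["year"]) else None,
        ))
    return out


def write_two_arm_counts(path: str | Path, tables: Iterable[TwoArmCounts]) -> None:
    pd.DataFrame([
        {"study_id": t.study_id, "quantity_id": t.quantity_id,
         "n_int": t.n_int, "k_int": t.k_int,
         "n_ctrl": t.n_ctrl, "k_ctrl": t.k_ctrl, "year": t.year}
        for t in tables
    ]).to_csv(path, index=False)


def gaussian_limit_check(arms: TwoArmCounts, threshold: float = 5.0) -> bool:
    """True iff min(n, np, n(1-p)) >= threshold in both arms (warn-only)."""
    for n, k in ((arms.n_int, arms.k_int), (arms.n_ctrl, arms.k_ctrl)):
        p = k / n
        if min(n, n * p, n * (1 - p)) < threshold:
            return False
    return True
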