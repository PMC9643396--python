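"""Non-compartmental pharmacokinetics and two-arm survival analysis.

NCA follows the classic formulas: Cmax/Tmax read off the observed (mean)
concentrations, AUC by the linear trapezoid rule, the terminal elimination
rate constant k_el as minus the OLS slope of ln C versus t over a terminal
point set, t1/2 = ln2/k_el, and AUC to infinity by adding C_last/k_el.
Terminal-set selection defaults to ``best_fit``: among all candidate tails
of >= 3 positive-concentration points starting after Tmax, take the one with
maximal adjusted r^2 (more points win ties).

Survival uses the Kaplan-Meier product-limit estimator and the two-group
log-rank test (hypergeometric variance), both via lifelines; the median is
the smallest time with S(t) <= 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = [
    "PKProfile",
    "NCAResult",
    "SurvivalRecord",
    "KMResult",
    "nca",
    "auc_trapezoid",
    "km_estimate",
    "logrank",
]


@dataclass
class PKProfile:
    """Concentration-time data; optional per-animal replicates per timepoint.

    ``time`` in hours, ``concentration`` in ng/ml.  With a destructive
    sampling design, pass ``replicates`` as a DataFrame with columns
    (time_h, conc_ng_ml, animal_id) and the per-time means are used.
    """

    time: np.ndarray
    concentration: np.ndarray
    replicates: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.time.shape != self.concentration.shape:
            raise AnalysisError("time and concentration must match in shape")
        if len(np.unique(self.time)) != self.time.size or np.any(self.time < 0):
            raise AnalysisError("times must be distinct and >= 0")
        if np.any(self.concentration < 0):
            raise AnalysisError("concentrations must be >= 0")
        order = np.argsort(self.time)
        self.time = self.time[order]
        self.concentration = self.concentration[order]

    @classmethod
    def from_replicates(cls, replicates: pd.DataFrame) -> "PKProfile":
        means = replicates.groupby("time_h")["conc_ng_ml"].mean()
        return cls(
            time=means.index.to_numpy(),
            concentration=means.to_numpy(),
            replicates=replicates,
        )


@dataclass
class NCAResult:
    cmax: float  # ng/ml
    tmax: float  # h (first time of the maximum)
    tmax_range: tuple[float, float]  # equal to (tmax, tmax) unless tied
    auc_0_t: float  # ng*h/ml, linear trapezoid to the last observation
    auc_0_inf: float | None
    kel: float | None  # 1/h
    t_half: float | None  # h
    terminal_points: int
    terminal_r2: float | None
    extrapolation_flagged: bool = False
    message: str = ""


@dataclass(frozen=True)
class SurvivalRecord:
    subject: str
    arm: str
    time: float  # weeks
    event: bool  # True = death observed, False = censored

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # per arm: columns time, survival
    medians: dict[str, float | None]  # None when S never reaches 0.5
    chi_square: float
    p_value: float


def auc_trapezoid(time: np.ndarray, conc: np.ndarray) -> float:
    """Linear trapezoid AUC over the observed grid."""
    return float(np.trapezoid(conc, time))


def _terminal_regression(t: np.ndarray, c: np.ndarray):
    """OLS of ln c on t; returns (kel, r2, adjusted r2)."""
    logc = np.log(c)
    n = len(t)
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    adj = r2 if n <= 2 else 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return -float(slope), r2, adj


def nca(
    profile: PKProfile,
    terminal_rule: str | int = "best_fit",
) -> NCAResult:
    """Non-compartmental analysis of a concentration-time profile.

    ``terminal_rule="best_fit"`` chooses the terminal set maximizing adjusted
    r^2 among tails of >= 3 positive points starting after Tmax; an integer
    selects a fixed number of final points.  Leading zero concentrations
    contribute to the AUC; trailing zeros are excluded from the terminal
    regression.  When no valid terminal fit exists the extrapolated
    quantities are absent and the result is flagged.
    """
    if profile.replicates is not None and profile.time.size == 0:
        profile = PKProfile.from_replicates(profile.replicates)
    t, c = profile.time, profile.concentration
    if t.size < 2:
        raise AnalysisError("NCA needs at least two timepoints")

    cmax = float(c.max())
    tied = np.isclose(c, cmax)
    tmax_times = t[tied]
    tmax = float(tmax_times[0])
    tmax_range = (float(tmax_times.min()), float(tmax_times.max()))

    auc_t = auc_trapezoid(t, c)

    # candidate terminal points: strictly after the (last tied) Tmax,
    # positive concentration, trailing zeros dropped by the positivity rule.
    # When Cmax sits at the first positive observation (no visible absorption
    # phase, an IV-like monotone profile) the peak itself belongs to the
    # terminal phase and is kept.
    positive_times = t[c > 0]
    monotone_from_start = positive_times.size > 0 and np.isclose(
        tmax_range[1], positive_times[0]
    )
    if monotone_from_start:
        after = (t >= tmax_range[1]) & (c > 0)
    else:
        after = (t > tmax_range[1]) & (c > 0)
    t_term, c_term = t[after], c[after]

    kel = r2 = None
    n_used = 0
    if isinstance(terminal_rule, int):
        if terminal_rule < 3:
            raise AnalysisError("fixed terminal rule needs >= 3 points")
        if len(t_term) >= terminal_rule:
            kel, r2, _ = _terminal_regression(
                t_term[-terminal_rule:], c_term[-terminal_rule:]
            )
            n_used = terminal_rule
    elif terminal_rule == "best_fit":
        best_adj = -np.inf
        # iterate from the longest tail to the shortest so ties in adjusted
        # r^2 resolve toward more points
        for start in range(0, len(t_term) - 2):
            cand_t, cand_c = t_term[start:], c_term[start:]
            k_cand, r2_cand, adj = _terminal_regression(cand_t, cand_c)
            if adj > best_adj + 1e-12:
                best_adj, kel, r2, n_used = adj, k_cand, r2_cand, len(cand_t)
    else:
        raise ValueError(f"unknown terminal_rule {terminal_rule!r}")

    if kel is None or kel <= 0 or n_used < 3:
        return NCAResult(
            cmax=cmax, tmax=tmax, tmax_range=tmax_range, auc_0_t=auc_t,
            auc_0_inf=None, kel=None, t_half=None,
            terminal_points=n_used, terminal_r2=r2,
            extrapolation_flagged=True,
            message="no valid terminal elimination fit (need >= 3 points after "
                    "Tmax with positive concentrations and kel > 0)",
        )
    c_last = float(c[c > 0][-1])
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        tmax_range=tmax_range,
        auc_0_t=auc_t,
        auc_0_inf=auc_t + c_last / kel,
        kel=kel,
        t_half=math.log(2.0) / kel,
        terminal_points=n_used,
        terminal_r2=r2,
    )


def _arm_frames(records: Sequence[SurvivalRecord]) -> dict[str, pd.DataFrame]:
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise AnalysisError("no survival records")
    arms = {arm: sub for arm, sub in df.groupby("arm")}
    for arm, sub in arms.items():
        if sub.empty:
            raise AnalysisError(f"arm {arm!r} is empty")
    return arms


def km_estimate(records: Sequence[SurvivalRecord]) -> KMResult:
    """Kaplan-Meier curves and medians per arm, plus the two-arm log-rank test.

    With a single arm the log-rank fields are NaN.  Medians use the smallest
    time with S(t) <= 0.5 and are None for arms whose curve never reaches
    0.5 (including all-censored arms).
    """
    from lifelines import KaplanMeierFitter

    arms = _arm_frames(records)
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float | None] = {}
    for arm, sub in arms.items():
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        surv = kmf.survival_function_.reset_index()
        surv.columns = ["time", "survival"]
        curves[arm] = surv
        med = kmf.median_survival_time_
        medians[arm] = None if not np.isfinite(med) else float(med)
    if len(arms) == 2:
        chi2, p = logrank(records)
    else:
        chi2, p = float("nan"), float("nan")
    return KMResult(curves=curves, medians=medians, chi_square=chi2, p_value=p)


def logrank(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    from lifelines.statistics import logrank_test

    arms = _arm_frames(records)
    if len(arms) != 2:
        raise AnalysisError("log-rank test requires exactly two arms")
    (_, a), (_, b) = sorted(arms.items())
    if int(a["event"].sum()) + int(b["event"].sum()) == 0:
        raise AnalysisError("log-rank test requires at least one event")
    result = logrank_test(
        a["time"], b["time"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    return float(result.test_statistic), float(result.p_value)
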