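"""Balance index and inferential statistics.

The study's balance index is VCOM_RMS: the root mean square of the
medio-lateral velocity of the whole-body COM over a trial's analysis window.
Successful and unsuccessful trials are compared with a Welch t-test, and the
per-trial RMS of the first angular-momentum component's weight is regressed
on VCOM_RMS, trial type and their interaction (ordinary least squares,
pooled across participants as in the original analysis).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


class CollinearityError(StatsError):
    """Raised when the regression design matrix is rank deficient."""


@dataclass(frozen=True)
class StabilityRecord:
    """Per-trial balance summary."""

    trial_id: str
    success: bool
    vcom_rms: float          # m/s
    pc1_weight_rms: float    # dimensionless (normalized-AM score units)

    def __post_init__(self):
        if self.vcom_rms < 0:
            raise StatsError("vcom_rms must be nonnegative")


def vcom_rms(vcom_y: np.ndarray, frame_times: np.ndarray | None = None,
             window: tuple[float, float] | None = None,
             demean: bool = False) -> float:
    """RMS of the ML COM velocity over the analysis window.

    Plain RMS by default — the index is an amplitude measure, not a
    dispersion; pass ``demean=True`` for the mean-removed variant.
    """
    v = np.asarray(vcom_y, dtype=float)
    if window is not None:
        if frame_times is None:
            raise StatsError("window selection requires frame_times")
        t = np.asarray(frame_times, dtype=float)
        mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
        v = v[mask]
    if v.size == 0:
        raise StatsError("empty analysis window")
    if demean:
        v = v - v.mean()
    return float(np.sqrt(np.mean(v ** 2)))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_ttest(a, b) -> WelchResult:
    """Two-sided Welch t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            # identical constants: no evidence of a difference
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise StatsError("both samples degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


_TERMS = ("intercept", "type", "vcom_rms", "type_x_vcom_rms")


@dataclass
class RegressionResult:
    """OLS fit of PC1-weight RMS on trial type, VCOM_RMS and interaction.

    Trial type is coded successful = 1, unsuccessful = 0, so the
    ``type_x_vcom_rms`` coefficient is the successful-trial slope increment.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    df_model: int
    df_resid: int
    rsquared: float
    rsquared_adj: float
    nobs: int

    @property
    def slope_unsuccessful(self) -> float:
        return float(self.params["vcom_rms"])

    @property
    def slope_successful(self) -> float:
        return float(self.params["vcom_rms"] + self.params["type_x_vcom_rms"])

    def summary(self) -> str:
        lines = [
            f"OLS: pc1_weight_rms ~ type + vcom_rms + type:vcom_rms   (n = {self.nobs})",
            f"  F({self.df_model}, {self.df_resid}) = {self.fvalue:.2f},"
            f" R^2 = {self.rsquared:.3f}, adj R^2 = {self.rsquared_adj:.3f}",
            f"  {'term':>16} {'beta':>10} {'se':>9} {'t':>8} {'p':>10}",
        ]
        for term in _TERMS:
            lines.append(
                f"  {term:>16} {self.params[term]:10.4f} {self.bse[term]:9.4f} "
                f"{self.tvalues[term]:8.2f} {self.pvalues[term]:10.3g}")
        lines.append(
            f"  slopes: successful = {self.slope_successful:.3f}, "
            f"unsuccessful = {self.slope_unsuccessful:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "beta": {t: float(self.params[t]) for t in _TERMS},
            "se": {t: float(self.bse[t]) for t in _TERMS},
            "t": {t: float(self.tvalues[t]) for t in _TERMS},
            "p": {t: float(self.pvalues[t]) for t in _TERMS},
            "F": float(self.fvalue), "df1": self.df_model, "df2": self.df_resid,
            "R2": float(self.rsquared), "R2adj": float(self.rsquared_adj),
            "n": self.nobs,
            "slope_successful": self.slope_successful,
            "slope_unsuccessful": self.slope_unsuccessful,
            "type_coding": {"successful": 1, "unsuccessful": 0},
        }


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {"trial_id": [r.trial_id for r in records],
         "success": [r.success for r in records],
         "vcom_rms": [r.vcom_rms for r in records],
         "pc1_weight_rms": [r.pc1_weight_rms for r in records]})


def pc1_weight_regression(records: list[StabilityRecord]) -> RegressionResult:
    """Pooled OLS of PC1-weight RMS on {type, VCOM_RMS, type x VCOM_RMS}."""
    if len(records) < 5:
        raise StatsError("need at least 5 records")
    frame = records_to_frame(records)
    if frame["success"].nunique() < 2:
        raise CollinearityError(
            "design rank deficient: only one trial type present "
            "('type' and 'type_x_vcom_rms' are collinear with the intercept)")
    kind = frame["success"].astype(float)
    design = pd.DataFrame({
        "intercept": 1.0,
        "type": kind,
        "vcom_rms": frame["vcom_rms"],
        "type_x_vcom_rms": kind * frame["vcom_rms"],
    })
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise CollinearityError(
            f"design rank {rank} < {design.shape[1]}; check vcom_rms variation "
            "within each trial type")
    fit = sm.OLS(frame["pc1_weight_rms"].to_numpy(), design).fit()
    return RegressionResult(
        params=fit.params, bse=fit.bse, tvalues=fit.tvalues, pvalues=fit.pvalues,
        fvalue=float(fit.fvalue), df_model=int(fit.df_model),
        df_resid=int(fit.df_resid), rsquared=float(fit.rsquared),
        rsquared_adj=float(fit.rsquared_adj), nobs=int(fit.nobs))
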