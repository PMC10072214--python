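"""Cox proportional-hazards model suite, C-index, KM and log-rank.

The prognostic comparison fits six Cox models on a cohort — Clinical,
RPC (5 radiomic PCs), DPC (5 dosiomic PCs), Radiomic+Clinical,
Dosiomic+Clinical and Radiomic+Dosiomic+Clinical, where the combined
models carry forward only the PCs with significant hazard ratios
(p < 0.05) from their single-modality fits — and ranks them by AIC
(2k - 2 ln L) and Harrell's concordance index.

The C-index here is the proportion of comparable pairs (T_j < T_i with
patient j uncensored) whose risk ordering eta_j > eta_i matches the
time ordering; ``strict`` tie mode counts risk ties as discordant,
``half`` (the Harrell convention, default) as 1/2.

Partial-likelihood maximization (Efron ties), Kaplan-Meier estimation
and the log-rank statistic are delegated to lifelines behind this
module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalData",
    "CoxFit",
    "KMCurve",
    "fit_cox",
    "aic",
    "c_index",
    "c_index_ci",
    "km_estimate",
    "logrank_test",
    "build_model_suite",
    "CLINICAL_COVARIATES",
]

#: conventional clinical model covariates (age continuous, stage as IVB-vs-rest)
CLINICAL_COVARIATES = ("gender", "age", "stage_ivb", "peripheral_invasion")


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival outcomes with optional named covariates."""

    time: np.ndarray  # months, > 0
    event: np.ndarray  # 1 = event observed, 0 = censored
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event).astype(int)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be matching 1D arrays")
        if np.any(time <= 0):
            raise ValueError("survival times must be positive")
        if not set(np.unique(event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if self.covariates is not None and len(self.covariates) != len(time):
            raise ValueError("covariate table length mismatch")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx) -> "SurvivalData":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        cov = None if self.covariates is None else self.covariates.iloc[idx]
        return SurvivalData(self.time[idx], self.event[idx], cov)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event})
        if self.covariates is not None:
            df = pd.concat([self.covariates.reset_index(drop=True), df], axis=1)
        return df


@dataclass
class CoxFit:
    """One fitted Cox model with per-covariate and model-level summaries."""

    covariates: list[str]
    coef: pd.Series
    hr: pd.Series
    hr_ci_lower: pd.Series
    hr_ci_upper: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    log_likelihood: float
    n_params: int
    aic: float
    c_index: float
    c_index_ci_95: tuple[float, float] | None
    linear_predictor: np.ndarray

    @property
    def significant(self) -> list[str]:
        """Covariates with p < 0.05."""
        return [c for c in self.covariates if self.p[c] < 0.05]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hr,
                "HR 95% lower": self.hr_ci_lower,
                "HR 95% upper": self.hr_ci_upper,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            }
        )


def fit_cox(
    data: SurvivalData,
    ci_boot: int = 0,
    seed: int = 0,
    tie_mode: str = "half",
) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron tie handling).

    Returns coefficient-level Wald statistics, the model AIC and the
    in-sample C-index of the linear predictor; ``ci_boot > 0`` adds a
    percentile-bootstrap 95% CI for the C-index.
    """
    if data.covariates is None or data.covariates.shape[1] == 0:
        raise ValueError("fit_cox needs at least one covariate")
    if data.event.sum() < 1:
        raise ValueError("fit_cox needs at least one observed event")
    df = data.frame()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                fit_options={"precision": 1e-10, "max_steps": 500},
            )
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    summ = cph.summary
    risk = df[list(data.covariates.columns)].to_numpy() @ cph.params_.to_numpy()
    ll = float(cph.log_likelihood_)
    k = len(cph.params_)
    ci = c_index_ci(risk, data, n_boot=ci_boot, seed=seed) if ci_boot else None
    return CoxFit(
        covariates=list(data.covariates.columns),
        coef=cph.params_.copy(),
        hr=np.exp(cph.params_).rename("HR"),
        hr_ci_lower=np.exp(summ["coef lower 95%"]).rename("lower"),
        hr_ci_upper=np.exp(summ["coef upper 95%"]).rename("upper"),
        se=summ["se(coef)"].copy(),
        z=summ["z"].copy(),
        p=summ["p"].copy(),
        log_likelihood=ll,
        n_params=k,
        aic=aic(ll, k),
        c_index=c_index(risk, data, tie_mode=tie_mode),
        c_index_ci_95=ci,
        linear_predictor=risk,
    )


def aic(log_likelihood: float, n_params: int) -> float:
    """Akaike information criterion, 2k - 2 ln(L)."""
    return 2.0 * n_params - 2.0 * log_likelihood


def c_index(risk: np.ndarray, data: SurvivalData, tie_mode: str = "half") -> float:
    """Concordance of a risk score with censored event times.

    Comparable pairs are (i, j) with T_j < T_i and delta_j = 1; a pair
    is concordant when eta_j > eta_i. Risk ties count 0 in ``strict``
    mode and 1/2 in ``half`` (Harrell) mode.
    """
    if tie_mode not in ("strict", "half"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    risk = np.asarray(risk, dtype=float)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    t, d = data.time, data.event
    comparable = (t[:, None] < t[None, :]) & (d[:, None] == 1)  # [j, i]
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs: cannot compute C-index")
    gt = risk[:, None] > risk[None, :]
    conc = (comparable & gt).sum()
    if tie_mode == "half":
        ties = (comparable & (risk[:, None] == risk[None, :])).sum()
        return float((conc + 0.5 * ties) / n_comp)
    return float(conc / n_comp)


def c_index_ci(
    risk: np.ndarray,
    data: SurvivalData,
    n_boot: int = 1000,
    seed: int = 0,
    tie_mode: str = "half",
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for the C-index (resampling patients)."""
    risk = np.asarray(risk, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(data)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(c_index(risk[idx], data.subset(idx), tie_mode=tie_mode))
        except ValueError:
            skipped += 1
    if not vals:
        raise ValueError("all bootstrap resamples were degenerate")
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate bootstrap resamples", stacklevel=2)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate on the event-time grid."""

    time: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censored: np.ndarray  # censoring counts at each grid time

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "censored": self.censored,
            }
        )


def km_estimate(data: SurvivalData) -> KMCurve:
    """Product-limit survival estimate (deaths precede censorings at ties)."""
    if len(data) < 1:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, data.event)
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    return KMCurve(
        time=times,
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(),
        censored=tbl["censored"].to_numpy(),
    )


def logrank_test(group_a: SurvivalData, group_b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square on 1 df, two-sided p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a.event.sum() + group_b.event.sum() == 0:
        raise ValueError("log-rank test undefined without any events")
    res = _ll_logrank(group_a.time, group_b.time, group_a.event, group_b.event)
    return float(res.test_statistic), float(res.p_value)


MODEL_NAMES = (
    "clinical",
    "radiomic",
    "dosiomic",
    "radiomic_clinical",
    "dosiomic_clinical",
    "radiomic_dosiomic_clinical",
)


def build_model_suite(
    rpc_scores: pd.DataFrame,
    dpc_scores: pd.DataFrame,
    clinical: pd.DataFrame,
    outcomes: SurvivalData,
    ci_boot: int = 0,
    seed: int = 0,
) -> dict[str, CoxFit]:
    """Fit the six-model comparison suite.

    Combined models reuse only the significant (p < 0.05) principal
    components of the single-modality fits; if none are significant the
    combined model degrades to the clinical covariates with a warning.
    """
    for tbl in (dpc_scores, clinical):
        if not rpc_scores.index.equals(tbl.index):
            raise ValueError("score/clinical tables must share patient ids")
    clin = clinical[list(CLINICAL_COVARIATES)]

    def fit(cov: pd.DataFrame) -> CoxFit:
        return fit_cox(
            SurvivalData(outcomes.time, outcomes.event, cov.reset_index(drop=True)),
            ci_boot=ci_boot,
            seed=seed,
        )

    fits: dict[str, CoxFit] = {}
    fits["clinical"] = fit(clin)
    fits["radiomic"] = fit(rpc_scores)
    fits["dosiomic"] = fit(dpc_scores)

    sig_rpc = fits["radiomic"].significant
    sig_dpc = fits["dosiomic"].significant
    if not sig_rpc and not sig_dpc:
        warnings.warn(
            "no significant principal components: combined models reduce to clinical",
            stacklevel=2,
        )
    fits["radiomic_clinical"] = fit(pd.concat([rpc_scores[sig_rpc], clin], axis=1))
    fits["dosiomic_clinical"] = fit(pd.concat([dpc_scores[sig_dpc], clin], axis=1))
    fits["radiomic_dosiomic_clinical"] = fit(
        pd.concat([rpc_scores[sig_rpc], dpc_scores[sig_dpc], clin], axis=1)
    )
    return fits
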