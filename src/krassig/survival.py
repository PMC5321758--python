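"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, score stratification.

Patients carrying a high signature score are compared against low scorers,
optionally within each mutation-status stratum, reproducing the
stratified Kaplan-Meier / multivariate Cox design used for genotype-linked
signatures.  Cox fitting and Kaplan-Meier estimation delegate to lifelines;
the log-rank (Mantel-Cox) statistic is computed explicitly so that the
per-event-time observed/expected decomposition is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalTable:
    """Per-patient follow-up data.

    ``time`` is positive follow-up time, ``event`` is 1 for death/progression
    and 0 for censoring.  Optional covariates (age in years, binary sex,
    ordinal stage), mutation ``status`` labels and a signature ``score`` may
    be absent; downstream fits restrict themselves to present columns.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    age: np.ndarray | None = None
    sex: np.ndarray | None = None
    stage: np.ndarray | None = None
    status: np.ndarray | None = None
    score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise SurvivalError("time/event length does not match sample_ids")
        if np.any(self.time <= 0):
            raise SurvivalError("all times must be positive")
        if not np.all(np.isin(self.event, [0, 1])):
            raise SurvivalError("events must be 0 or 1")
        for name in ("age", "sex", "stage", "score"):
            col = getattr(self, name)
            if col is not None:
                setattr(self, name, np.asarray(col, dtype=float))
        if self.status is not None:
            self.status = np.asarray(self.status, dtype=object)

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def covariates_present(self) -> list[str]:
        return [c for c in ("age", "sex", "stage", "score") if getattr(self, c) is not None]

    def to_frame(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        for name in ("age", "sex", "stage", "status", "score"):
            col = getattr(self, name)
            if col is not None:
                data[name] = col
        return pd.DataFrame(data)

    def with_scores(self, scores: dict[str, float]) -> "SurvivalTable":
        missing = [s for s in self.sample_ids if s not in scores]
        if missing:
            raise SurvivalError(f"no score for samples {missing[:5]}")
        new = SurvivalTable(
            sample_ids=list(self.sample_ids),
            time=self.time.copy(),
            event=self.event.copy(),
            age=None if self.age is None else self.age.copy(),
            sex=None if self.sex is None else self.sex.copy(),
            stage=None if self.stage is None else self.stage.copy(),
            status=None if self.status is None else self.status.copy(),
            score=np.array([scores[s] for s in self.sample_ids], dtype=float),
        )
        return new


@dataclass
class KMEstimate:
    """Product-limit estimator: S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def restricted_mean(self, horizon: float | None = None) -> float:
        """Area under the step function up to ``horizon`` (default: last time)."""
        if horizon is None:
            horizon = float(self.times[-1]) if len(self.times) else 0.0
        grid = np.concatenate([[0.0], self.times[self.times <= horizon], [horizon]])
        surv = np.concatenate([[1.0], self.survival[self.times <= horizon], [self.survival_at(horizon)]])
        return float(np.sum(np.diff(grid) * surv[:-1]))


def km_estimate(table: SurvivalTable) -> KMEstimate:
    """Kaplan-Meier estimate with risk/event counts at each distinct event time."""
    if len(table) == 0:
        raise SurvivalError("empty table")
    kmf = KaplanMeierFitter()
    kmf.fit(table.time, table.event)
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    if len(times) == 0:
        return KMEstimate(
            times=np.array([]), survival=np.array([]),
            n_at_risk=np.array([], dtype=int), n_events=np.array([], dtype=int),
        )
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMEstimate(
        times=times,
        survival=surv,
        n_at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
    )


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    observed: np.ndarray   # per-group observed event counts
    expected: np.ndarray   # per-group expected event counts under H0


def logrank_test(table: SurvivalTable, group: np.ndarray | list) -> LogrankResult:
    """Mantel-Cox log-rank test between two groups.

    At each distinct event time the expected events per group come from the
    hypergeometric mean and the variance from the hypergeometric variance;
    the statistic is (sum O - sum E)^2 / sum V on 1 df.
    """
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise SurvivalError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    if table.event.sum() == 0:
        raise SurvivalError("log-rank undefined with no events")
    time, event = table.time, table.event
    in_g1 = group == levels[1]
    event_times = np.unique(time[event == 1])
    O1 = E1 = V = 0.0
    obs = np.zeros(2)
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in_g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & in_g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        obs[0] += d - d1
        obs[1] += d1
    if V == 0:
        chi2 = 0.0
    else:
        chi2 = (O1 - E1) ** 2 / V
    total = obs.sum()
    expected = np.array([total - E1, E1])
    return LogrankResult(
        chi_square=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
        observed=obs,
        expected=expected,
    )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: per-covariate effects plus diagnostics."""

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_value: np.ndarray
    log_likelihood: float
    converged: bool = True
    flagged: bool = False
    message: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_value,
            },
            index=self.covariates,
        )


def cox_fit(table: SurvivalTable, covariates: list[str]) -> CoxFit:
    """Multivariate Cox PH fit (Efron ties) with Wald confidence intervals.

    Non-convergence or separation (monotone likelihood) is reported as a
    flagged fit rather than an exception.
    """
    if table.event.sum() == 0:
        raise SurvivalError("Cox fit requires at least one event")
    frame = table.to_frame()
    for cov in covariates:
        if cov not in frame.columns:
            raise SurvivalError(f"covariate {cov!r} absent from table")
        if np.ptp(frame[cov].to_numpy(dtype=float)) == 0:
            raise SurvivalError(f"covariate {cov!r} is constant")
    df = frame[["time", "event", *covariates]].astype(float)
    fitter = CoxPHFitter()
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # monotone likelihood / singularities
        nan = np.full(len(covariates), np.nan)
        return CoxFit(
            covariates=list(covariates), beta=nan, se=nan, hr=nan,
            ci_lower=nan, ci_upper=nan, p_value=nan,
            log_likelihood=np.nan, converged=False, flagged=True, message=str(exc),
        )
    beta = fitter.params_.reindex(covariates).to_numpy()
    se = fitter.standard_errors_.reindex(covariates).to_numpy()
    flagged = bool(np.any(np.abs(beta) > 20) or np.any(~np.isfinite(se)))
    return CoxFit(
        covariates=list(covariates),
        beta=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=np.exp(beta - 1.96 * se),
        ci_upper=np.exp(beta + 1.96 * se),
        p_value=fitter.summary["p"].reindex(covariates).to_numpy(),
        log_likelihood=float(fitter.log_likelihood_),
        converged=True,
        flagged=flagged,
        message="possible separation (diverging coefficient)" if flagged else "",
    )


def stratify_by_score(
    table: SurvivalTable,
    quantile: float = 0.5,
    within_status: bool = False,
) -> np.ndarray:
    """Label each patient high (score > quantile threshold) or low.

    Ties at the threshold go to ``low``.  With ``within_status=True`` the
    threshold is computed separately inside each mutation-status stratum so
    that the high/low split is balanced per genotype.
    """
    if table.score is None:
        raise SurvivalError("table carries no scores")
    if not 0 < quantile < 1:
        raise SurvivalError("quantile must be in (0,1)")
    scores = table.score
    labels = np.empty(len(table), dtype=object)
    if within_status:
        if table.status is None:
            raise SurvivalError("within-status stratification requires status labels")
        strata = [(table.status == s) for s in np.unique(table.status.astype(str))]
    else:
        strata = [np.ones(len(table), dtype=bool)]
    for mask in strata:
        sub = scores[mask]
        if np.ptp(sub) == 0:
            raise SurvivalError("cannot stratify: constant scores within stratum")
        threshold = np.quantile(sub, quantile)
        labels[mask] = np.where(sub > threshold, "high", "low")
    return labels
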