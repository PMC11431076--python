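"""Recurrence-free-survival statistics: Cox screening and stepwise modeling,
Kaplan–Meier + log-rank, Fisher's exact test, and the two-factor Relapse Score.

Cox partial-likelihood maximization is delegated to
:class:`statsmodels.duration.hazard_regression.PHReg` (Breslow tie handling
by default, Efron available); Kaplan–Meier estimation and the log-rank test
to ``lifelines``.  The stepwise likelihood-ratio selection, the univariate
screen and the Relapse Score construction are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SD_CUTOFF = 5.8
Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model.

    Per-covariate arrays are aligned with ``covariates``; ``hr`` is
    ``exp(estimate)`` and the 95% CI is Wald, ``exp(estimate ± 1.96·SE)``.
    ``lr_chi2``/``lr_p`` test the model against the null (no-covariate)
    partial likelihood.
    """

    covariates: list[str]
    estimates: np.ndarray
    se: np.ndarray
    wald_chi2: np.ndarray
    p_values: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    lr_chi2: float
    lr_p: float
    n: int
    n_events: int
    ties: str
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        """Table 2-style summary: estimate, SE, chi-square, p, HR, 95% CI."""
        return pd.DataFrame({
            "covariate": self.covariates,
            "estimate": self.estimates,
            "se": self.se,
            "chi_square": self.wald_chi2,
            "p_value": self.p_values,
            "hazard_ratio": self.hr,
            "hr_ci_low": self.ci_low,
            "hr_ci_high": self.ci_high,
        })

    def as_dict(self) -> dict:
        d = {"covariates": self.covariates, "ties": self.ties,
             "converged": self.converged, "n": self.n, "n_events": self.n_events,
             "log_likelihood": self.log_likelihood,
             "null_log_likelihood": self.null_log_likelihood,
             "lr_chi2": self.lr_chi2, "lr_p": self.lr_p}
        d["table"] = self.summary().to_dict(orient="records")
        return d


def cox_fit(table: pd.DataFrame, covariates: list[str],
            time_col: str = "rfs_days", event_col: str = "event",
            ties: str = "breslow") -> CoxFit:
    """Fit a Cox model by maximizing the partial likelihood.

    Raises ``ValueError`` for constant covariates or a cohort without
    events.  Monotone likelihood (perfect separation) is returned as a
    flagged non-convergent fit, not an exception.
    """
    from statsmodels.duration.hazard_regression import PHReg

    t = np.asarray(table[time_col], dtype=float)
    e = np.asarray(table[event_col], dtype=float)
    if e.sum() < 1:
        raise ValueError("no events in the cohort; Cox model undefined")
    X = np.column_stack([np.asarray(table[c], dtype=float) for c in covariates])
    const = [c for c, col in zip(covariates, X.T) if np.ptp(col) == 0]
    if const:
        raise ValueError(f"constant covariate(s): {const}")

    model = PHReg(t, X, status=e, ties=ties)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=100)
        except Exception:
            converged = False
            res = model.fit(maxiter=100, method="bfgs", disp=False)
    params = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    # monotone likelihood drives |beta| and SE to infinity
    if not np.all(np.isfinite(se)) or np.any(np.abs(params) > 15) or np.any(se > 50):
        converged = False

    llf = float(model.loglike(params))
    llf0 = float(model.loglike(np.zeros(len(covariates))))
    lr = max(0.0, 2.0 * (llf - llf0))
    wald = (params / se) ** 2
    # a flagged non-convergent fit may carry diverging estimates; its CI
    # bounds then overflow to inf, which is the honest answer
    with np.errstate(over="ignore"):
        hr = np.exp(params)
        ci_low = np.exp(params - Z95 * se)
        ci_high = np.exp(params + Z95 * se)
    return CoxFit(
        covariates=list(covariates),
        estimates=params,
        se=se,
        wald_chi2=wald,
        p_values=stats.chi2.sf(wald, df=1),
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        log_likelihood=llf,
        null_log_likelihood=llf0,
        lr_chi2=lr,
        lr_p=float(stats.chi2.sf(lr, df=len(covariates))),
        n=len(t),
        n_events=int(e.sum()),
        ties=ties,
        converged=converged,
    )


def univariate_screen(table: pd.DataFrame, candidates: list[str],
                      time_col: str = "rfs_days", event_col: str = "event",
                      ties: str = "breslow") -> pd.DataFrame:
    """One single-covariate Cox fit per candidate; Wald and LR p per row."""
    rows = []
    for c in candidates:
        try:
            f = cox_fit(table, [c], time_col, event_col, ties)
            rows.append({"covariate": c, "estimate": f.estimates[0],
                         "se": f.se[0], "hazard_ratio": f.hr[0],
                         "wald_p": f.p_values[0], "lr_p": f.lr_p,
                         "converged": f.converged})
        except ValueError as err:
            rows.append({"covariate": c, "estimate": np.nan, "se": np.nan,
                         "hazard_ratio": np.nan, "wald_p": np.nan,
                         "lr_p": np.nan, "converged": False,
                         "note": str(err)})
    return pd.DataFrame(rows)


@dataclass
class StepwiseResult:
    """Stepwise-LR selection outcome: final fit plus the selection path."""

    fit: CoxFit | None
    selected: list[str]
    path: list[dict] = field(default_factory=list)
    screen: pd.DataFrame | None = None
    status: str = "ok"


def stepwise_lr(table: pd.DataFrame, candidates: list[str],
                alpha_enter: float = 0.05, alpha_stay: float = 0.05,
                time_col: str = "rfs_days", event_col: str = "event",
                ties: str = "breslow", screen: bool = True) -> StepwiseResult:
    """Forward stepwise Cox selection by likelihood-ratio testing.

    Candidates are first screened by univariate Cox (p < ``alpha_enter``
    gate) when ``screen`` is set.  At each step the candidate with the
    largest significant 1-df LR improvement enters; included covariates are
    then re-tested and removed when their LR contribution has p >
    ``alpha_stay``.  The procedure is deterministic given the table (ties in
    LR improvement break toward the earlier candidate in ``candidates``).
    """
    path: list[dict] = []
    screen_tbl = None
    pool = list(candidates)
    if screen:
        screen_tbl = univariate_screen(table, pool, time_col, event_col, ties)
        pool = [c for c, p in zip(screen_tbl["covariate"], screen_tbl["wald_p"])
                if np.isfinite(p) and p < alpha_enter]
        path.append({"step": "screen", "passed": list(pool)})
        if not pool:
            return StepwiseResult(fit=None, selected=[], path=path,
                                  screen=screen_tbl,
                                  status="no candidate passed univariate screening")

    selected: list[str] = []
    current_llf = None
    while True:
        best = None
        for c in pool:
            if c in selected:
                continue
            try:
                f = cox_fit(table, selected + [c], time_col, event_col, ties)
            except ValueError:
                continue
            base_llf = (current_llf if current_llf is not None
                        else f.null_log_likelihood)
            lr = 2.0 * (f.log_likelihood - base_llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if p < alpha_enter and (best is None or lr > best[1] + 1e-12):
                best = (c, lr, p, f)
        if best is None:
            break
        c, lr, p, f = best
        selected.append(c)
        current_llf = f.log_likelihood
        path.append({"step": "add", "covariate": c, "lr_chi2": lr, "p": p})

        # backward re-check of earlier inclusions
        removed = True
        while removed and len(selected) > 1:
            removed = False
            full = cox_fit(table, selected, time_col, event_col, ties)
            for c_out in list(selected):
                reduced = cox_fit(table, [c for c in selected if c != c_out],
                                  time_col, event_col, ties)
                lr_out = 2.0 * (full.log_likelihood - reduced.log_likelihood)
                p_out = float(stats.chi2.sf(max(lr_out, 0.0), df=1))
                if p_out > alpha_stay:
                    selected.remove(c_out)
                    path.append({"step": "remove", "covariate": c_out,
                                 "lr_chi2": lr_out, "p": p_out})
                    current_llf = reduced.log_likelihood
                    removed = True
                    break

    if not selected:
        return StepwiseResult(fit=None, selected=[], path=path, screen=screen_tbl,
                              status="no covariate entered the model")
    final = cox_fit(table, selected, time_col, event_col, ties)
    return StepwiseResult(fit=final, selected=selected, path=path,
                          screen=screen_tbl)


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


@dataclass
class KMResult:
    """Per-group product-limit curves with the 2-group log-rank test."""

    groups: list
    curves: dict  # group -> DataFrame(time, survival)
    chi2: float
    p_value: float
    n_per_group: dict


def km_logrank(times, events, groups) -> KMResult:
    """Kaplan–Meier curves per group plus the standard log-rank chi-square.

    Requires ≥2 nonempty groups.  The p-value is the 1-df chi-square tail
    for two groups (k−1 df in general).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank needs at least two groups")
    curves = {}
    n_per = {}
    for g in labels:
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf.iloc[:, 0].to_numpy()})
        n_per[g] = int(sel.sum())
    res = multivariate_logrank_test(times, groups, events)
    return KMResult(groups=list(labels), curves=curves,
                    chi2=float(res.test_statistic), p_value=float(res.p_value),
                    n_per_group=n_per)


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on table ((a, b), (c, d)).

    p sums hypergeometric probabilities of all tables with fixed margins
    whose probability does not exceed the observed one (minimum-likelihood
    rule).  Returns ``(odds_ratio, p)``; the odds ratio is ad/bc, NaN when
    b·c = 0 (flagged undefined, not infinity).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    oratio = (a * d) / (b * c) if b * c > 0 else float("nan")
    return oratio, float(p)


# ---------------------------------------------------------------------------
# Relapse Score


@dataclass(frozen=True)
class RiskScore:
    """Two-factor relapse risk score: R1 margin flag + low edge-SD flag."""

    r1_flag: int
    low_sd_flag: int

    @property
    def score(self) -> int:
        return self.r1_flag + self.low_sd_flag


def relapse_score(margin: str, edge_sd: float,
                  cutoff: float = DEFAULT_SD_CUTOFF) -> RiskScore | None:
    """Score = (margin == R1) + (edge_sd < cutoff); None when edge_sd missing.

    The cutoff defaults to 5.8 on the raw edge SD and is never re-estimated
    from the data.
    """
    if margin not in ("R0", "R1"):
        raise ValueError(f"margin must be 'R0' or 'R1', got {margin!r}")
    if edge_sd is None or not np.isfinite(edge_sd):
        return None
    return RiskScore(r1_flag=int(margin == "R1"),
                     low_sd_flag=int(edge_sd < cutoff))


def score_table(table: pd.DataFrame, margin_col: str = "margin",
                sd_col: str = "edge_sd",
                cutoff: float = DEFAULT_SD_CUTOFF) -> pd.DataFrame:
    """Vectorized relapse score over a cohort table (adds a ``score`` column)."""
    out = table.copy()
    scores = []
    for m, s in zip(out[margin_col], out[sd_col]):
        rs = relapse_score(m, s, cutoff)
        scores.append(np.nan if rs is None else rs.score)
    out["score"] = scores
    return out


def score_stratification(table: pd.DataFrame, score_col: str = "score",
                         time_col: str = "rfs_days",
                         event_col: str = "event") -> dict[str, KMResult | None]:
    """The two pre-registered score contrasts: {0} vs {1,2} and {0,1} vs {2}.

    A contrast with an empty side is skipped (None) with no other grouping
    attempted.
    """
    tab = table[table[score_col].notna()]
    s = tab[score_col].to_numpy()
    out: dict[str, KMResult | None] = {}
    for name, split in (("0_vs_12", s >= 1), ("01_vs_2", s >= 2)):
        if split.all() or (~split).all():
            out[name] = None
            continue
        labels = np.where(split, "high", "low")
        out[name] = km_logrank(tab[time_col], tab[event_col], labels)
    return out
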