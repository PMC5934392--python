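"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, treatment interaction.

Kaplan-Meier curves and the log-rank test delegate to lifelines.  Cox
proportional-hazards regression is implemented here as a Newton-Raphson
maximizer of the partial likelihood with both Efron and Breslow tie
handling, Wald confidence intervals on the log-hazard scale, and a
likelihood-ratio test against the null model (the headline p-value).  The
score test at beta=0 with Breslow ties reproduces the log-rank statistic
exactly, which doubles as an internal consistency check.

The treatment-interaction analysis fits recurrence-free survival against
subtype, chemotherapy, their product, and sex/age/stage; the interaction
p-value is the likelihood-ratio test of the product term, and per-subtype
chemotherapy hazard ratios come from stratified fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .containers import EP, MP, STAGES, SubtypeLabels, ValidationError


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    fitters: dict               # group -> fitted KaplanMeierFitter

    def survival_at(self, t: float, group=None):
        """Step-function S(t); returns (value, beyond_last_observation)."""
        if group is None:
            group = next(iter(self.fitters))
        kmf = self.fitters[group]
        last = kmf.durations.max()
        value = float(kmf.predict(t))
        return value, bool(t > last)

    def survival_table(self, group=None) -> pd.DataFrame:
        if group is None:
            group = next(iter(self.fitters))
        return self.fitters[group].survival_function_


def km_estimate(times, events, groups=None) -> KMResult:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValidationError("negative survival times")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    fitters = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() < 1:
            raise ValidationError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        fitters[g] = kmf
    return KMResult(fitters)


@dataclass
class LogrankResult:
    chi2: float
    p: float
    df: int
    zero_events: bool = False


def logrank_test(times, events, groups) -> LogrankResult:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValidationError("log-rank test needs >= 2 groups")
    df = len(pd.unique(groups)) - 1
    if events.sum() == 0:
        return LogrankResult(chi2=0.0, p=1.0, df=df, zero_events=True)
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value), df=df)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def _cox_terms(beta, X, time, event, ties):
    """Log partial likelihood, gradient and observed information.

    Inputs must be sorted by ascending time; ties within a time share one
    risk set.  Computation is vectorized (Breslow); the Efron correction
    loops over tied event times only.
    """
    n, p = X.shape
    eta = X @ beta
    c = eta.max() if n else 0.0
    w = np.exp(eta - c)
    # suffix sums: S*[k] = sum over samples with time >= time[k]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1],
                   axis=0)[::-1]
    first = np.searchsorted(time, time, side="left")
    e = event.astype(bool)
    pos = first[e]
    s0 = S0[pos]
    m1 = S1[pos] / s0[:, None]
    ll = eta[e].sum() - (np.log(s0).sum() + e.sum() * c)
    grad = X[e].sum(axis=0) - m1.sum(axis=0)
    info = (S2[pos] / s0[:, None, None]).sum(axis=0) - m1.T @ m1

    if ties == "efron":
        # replace the Breslow contribution of tied event-time groups
        ev_pos, counts = np.unique(pos, return_counts=True)
        for k, d in zip(ev_pos[counts > 1], counts[counts > 1]):
            tied = e & (first == k)
            wI, XI = w[tied], X[tied]
            d0 = wI.sum()
            d1 = wI @ XI
            d2 = np.einsum("i,ij,ik->jk", wI, XI, XI)
            # remove Breslow terms for this group
            m1k = S1[k] / S0[k]
            ll += d * np.log(S0[k])
            grad += d * m1k
            info -= d * (S2[k] / S0[k] - np.outer(m1k, m1k))
            for l in range(d):
                f = l / d
                denom = S0[k] - f * d0
                mk = (S1[k] - f * d1) / denom
                ll -= np.log(denom)
                grad -= mk
                info += (S2[k] - f * d2) / denom - np.outer(mk, mk)
    elif ties != "breslow":
        raise ValidationError("ties must be 'efron' or 'breslow'")
    return ll, grad, info


def _sorted_arrays(X, time, event):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order]


def cox_loglik(beta, X, time, event, ties="efron") -> float:
    """Log partial likelihood at ``beta`` (public for oracles/diagnostics)."""
    Xs, ts, es = _sorted_arrays(X, time, event)
    return float(_cox_terms(np.asarray(beta, float), Xs, ts, es, ties)[0])


def cox_score_test(x, time, event, ties="breslow") -> float:
    """Score chi-square at beta=0; with Breslow ties and a group indicator
    this equals the log-rank statistic."""
    Xs, ts, es = _sorted_arrays(x, time, event)
    p = Xs.shape[1]
    _, g, info = _cox_terms(np.zeros(p), Xs, ts, es, ties)
    return float(g @ np.linalg.solve(info, g))


@dataclass
class CoxFit:
    coef: pd.Series
    se: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    wald_p: pd.Series
    lrt_stat: float
    lrt_p: float
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    warnings_: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hazard_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "wald_p": self.wald_p,
            }
        )


SEPARATION_BOUND = 15.0   # |coef| beyond this is a monotone-likelihood flag


def fit_cox_arrays(X, time, event, names=None, ties="efron", tol=1e-9,
                   max_iter=50) -> CoxFit:
    """Newton-Raphson fit of the Cox model on raw arrays."""
    Xs, ts, es = _sorted_arrays(X, time, event)
    n, p = Xs.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if es.sum() < p + 1:
        raise ValidationError(f"needs >= {p + 1} events, got {es.sum()}")
    if np.any(Xs.std(axis=0) == 0):
        raise ValidationError("constant covariate in Cox design")

    beta = np.zeros(p)
    ll, grad, info = _cox_terms(beta, Xs, ts, es, ties)
    ll_null = ll
    trace = [ll]
    converged = False
    warns = []
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}", trace)
        new_beta = beta + step
        new = _cox_terms(new_beta, Xs, ts, es, ties)
        halvings = 0
        while new[0] < ll - 1e-12 and halvings < 25:
            step = step / 2.0
            new_beta = beta + step
            new = _cox_terms(new_beta, Xs, ts, es, ties)
            halvings += 1
        delta = abs(new[0] - ll)
        beta, (ll, grad, info) = new_beta, new
        trace.append(ll)
        if delta / (abs(ll) + 1.0) < tol:
            converged = True
            break
    if np.abs(beta).max() > SEPARATION_BOUND:
        warns.append(
            "monotone likelihood: a coefficient diverged (complete separation?)"
        )
        converged = True        # flagged, not fatal
    if not converged:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; trace={trace}", trace
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    lrt = max(2.0 * (ll - ll_null), 0.0)
    coef = pd.Series(beta, index=names)
    se = pd.Series(se, index=names)
    with np.errstate(over="ignore"):   # separation yields infinite CI bounds
        hr = np.exp(coef)
        lo = np.exp(coef - z * se)
        hi = np.exp(coef + z * se)
    return CoxFit(
        coef=coef,
        se=se,
        hazard_ratios=hr,
        ci_lower=lo,
        ci_upper=hi,
        wald_p=pd.Series(2 * stats.norm.sf(np.abs(coef / se)), index=names),
        lrt_stat=float(lrt),
        lrt_p=float(stats.chi2.sf(lrt, p)),
        loglik=float(ll),
        loglik_null=float(ll_null),
        n=n,
        n_events=int(es.sum()),
        n_iter=it,
        converged=converged,
        warnings_=warns,
    )


def encode_covariates(data: pd.DataFrame, covariates,
                      stage_coding: str = "numeric") -> pd.DataFrame:
    """Numeric design columns from clinical fields.

    ``stage`` becomes ordered 1-4 by default or three stage dummies
    (reference I) with ``stage_coding="categorical"``; ``sex`` becomes an
    indicator for male; ``subtype`` an indicator for MP.  Numeric columns
    pass through.
    """
    out = {}
    for cov in covariates:
        if cov == "stage":
            stage_num = data["stage"].map({s: i + 1 for i, s in enumerate(STAGES)})
            if stage_num.isna().any():
                raise ValidationError("unknown stage value")
            if stage_coding == "numeric":
                out["stage"] = stage_num.astype(float)
            elif stage_coding == "categorical":
                for s in STAGES[1:]:
                    out[f"stage_{s}"] = (data["stage"] == s).astype(float)
            else:
                raise ValidationError("stage_coding must be 'numeric' or 'categorical'")
        elif cov == "sex":
            out["sex_m"] = (data["sex"] == "M").astype(float)
        elif cov == "subtype":
            out["subtype_mp"] = (data["subtype"] == MP).astype(float)
        else:
            col = pd.to_numeric(data[cov], errors="raise")
            out[cov] = col.astype(float)
    return pd.DataFrame(out, index=data.index)


def cox_fit(clinical: pd.DataFrame, covariates, endpoint: str = "RFS",
            ties: str = "efron", stage_coding: str = "numeric") -> CoxFit:
    """Cox PH regression of OS or RFS on clinical covariates."""
    if endpoint not in ("OS", "RFS"):
        raise ValidationError("endpoint must be 'OS' or 'RFS'")
    tcol, ecol = (f"{endpoint.lower()}_time", f"{endpoint.lower()}_event")
    design = encode_covariates(clinical, covariates, stage_coding=stage_coding)
    return fit_cox_arrays(
        design.to_numpy(float),
        clinical[tcol].to_numpy(float),
        clinical[ecol].to_numpy(int),
        names=list(design.columns),
        ties=ties,
    )


# ---------------------------------------------------------------------------
# Study-specific compositions
# ---------------------------------------------------------------------------

def subset_for_adjuvant_analysis(clinical: pd.DataFrame) -> pd.DataFrame:
    """Stage II-IV disease without distant metastasis (adjuvant-benefit subset)."""
    for col in ("stage", "distant_metastasis"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table lacks {col}")
    keep = clinical["stage"].isin(["II", "III", "IV"]) & (
        clinical["distant_metastasis"] == 0
    )
    return clinical.loc[keep].copy()


@dataclass
class InteractionResult:
    hr_chemo_ep: float
    ci_chemo_ep: tuple
    p_chemo_ep: float
    hr_chemo_mp: float
    ci_chemo_mp: tuple
    p_chemo_mp: float
    interaction_coef: float
    interaction_p: float
    full_fit: CoxFit
    reduced_fit: CoxFit


def _merge_labels(clinical: pd.DataFrame, labels: SubtypeLabels) -> pd.DataFrame:
    data = clinical.set_index("sample_id", drop=False)
    merged = data.join(labels.labels.rename("subtype"), how="inner")
    if merged.empty:
        raise ValidationError("no overlap between clinical table and labels")
    return merged


def interaction_test(clinical: pd.DataFrame, labels: SubtypeLabels,
                     ties: str = "efron",
                     stage_coding: str = "numeric") -> InteractionResult:
    """Subtype x chemotherapy interaction on RFS, adjusted for sex/age/stage.

    The interaction p-value is the likelihood-ratio test of the product
    term; per-subtype chemotherapy hazard ratios come from chemo-only fits
    within each subtype stratum (the stratified view of the same data).
    """
    data = _merge_labels(clinical, labels)
    for subtype in (MP, EP):
        for arm in (0, 1):
            if ((data["subtype"] == subtype) & (data["chemo"] == arm)).sum() == 0:
                raise ValidationError(
                    f"empty stratum: subtype={subtype}, chemo={arm}"
                )
    data = data.assign(
        subtype_x_chemo=((data["subtype"] == MP) & (data["chemo"] == 1)).astype(float)
    )
    base = ["subtype", "chemo", "sex", "age", "stage"]
    full = cox_fit(data, base + ["subtype_x_chemo"], endpoint="RFS", ties=ties,
                   stage_coding=stage_coding)
    reduced = cox_fit(data, base, endpoint="RFS", ties=ties,
                      stage_coding=stage_coding)
    lrt = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    interaction_p = float(stats.chi2.sf(lrt, 1))

    strata = {}
    for subtype in (MP, EP):
        sub = data.loc[data["subtype"] == subtype]
        fit = cox_fit(sub, ["chemo"], endpoint="RFS", ties=ties)
        strata[subtype] = fit
    return InteractionResult(
        hr_chemo_ep=float(strata[EP].hazard_ratios["chemo"]),
        ci_chemo_ep=(float(strata[EP].ci_lower["chemo"]),
                     float(strata[EP].ci_upper["chemo"])),
        p_chemo_ep=float(strata[EP].lrt_p),
        hr_chemo_mp=float(strata[MP].hazard_ratios["chemo"]),
        ci_chemo_mp=(float(strata[MP].ci_lower["chemo"]),
                     float(strata[MP].ci_upper["chemo"])),
        p_chemo_mp=float(strata[MP].lrt_p),
        interaction_coef=float(full.coef["subtype_x_chemo"]),
        interaction_p=interaction_p,
        full_fit=full,
        reduced_fit=reduced,
    )


def km_by_stage(clinical: pd.DataFrame, labels: SubtypeLabels,
                endpoint: str = "RFS") -> pd.DataFrame:
    """Per-AJCC-stage log-rank comparison of MP vs EP survival."""
    data = _merge_labels(clinical, labels)
    tcol, ecol = (f"{endpoint.lower()}_time", f"{endpoint.lower()}_event")
    rows = []
    for stage in STAGES:
        sub = data.loc[data["stage"] == stage]
        n_mp = (sub["subtype"] == MP).sum()
        n_ep = (sub["subtype"] == EP).sum()
        if n_mp == 0 or n_ep == 0:
            rows.append({"stage": stage, "n_mp": n_mp, "n_ep": n_ep,
                         "chi2": np.nan, "p": np.nan,
                         "note": "skipped: single subtype in stratum"})
            continue
        res = logrank_test(sub[tcol], sub[ecol], sub["subtype"])
        rows.append({"stage": stage, "n_mp": n_mp, "n_ep": n_ep,
                     "chi2": res.chi2, "p": res.p, "note": ""})
    return pd.DataFrame(rows).set_index("stage")
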