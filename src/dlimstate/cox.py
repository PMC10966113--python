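"""Transition-specific Cox proportional-hazards regression.

Fits the partial likelihood on counting-process data — rows ``(Tstart,
Tstop, status]`` with covariates constant on each interval, so time-varying
covariates enter through row splitting — by Newton–Raphson with analytic
gradient and Hessian.  Ties are handled by the Efron approximation (default)
or Breslow; the baseline cumulative hazard is always the Breslow form at the
reference covariate pattern.  Inference is Wald: CI = exp(beta +- z*SE),
two-sided normal p-values.

Models are complete-case: every row of a patient with an unknown level in
any model covariate is excluded before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .timelines import UNKNOWN

__all__ = [
    "CoxTransitionModel",
    "CoxTransitionResults",
    "complete_cases",
    "fit_cox",
    "REFERENCE_LEVELS",
    "LEVEL_ORDER",
    "MonotoneLikelihoodWarning",
]

#: reference category per covariate (the denominator of every hazard ratio)
REFERENCE_LEVELS = {
    "conditioning_donor": "MAC_RD",
    "chimerism_cat": "FDC",
    "alc_cat3": "ge1000",
    "alc_cat2": "ge1000",
    "viral": "none",
}

LEVEL_ORDER = {
    "conditioning_donor": ("MAC_RD", "MAC_UD", "RIC_RD", "RIC_UD"),
    "chimerism_cat": ("FDC", "lowMC", "highMC"),
    "alc_cat3": ("ge1000", "c500_999", "lt500"),
    "alc_cat2": ("ge1000", "lt1000"),
    "viral": ("none", "early", "late_onset"),
}


class MonotoneLikelihoodWarning(UserWarning):
    """The partial likelihood is monotone: an estimate diverges to +-inf."""


class CollinearDesignError(ValueError):
    def __init__(self, column):
        self.column = column
        super().__init__(f"design column {column!r} is aliased (constant or collinear)")


def complete_cases(
    table: pd.DataFrame, covariates: tuple[str, ...]
) -> tuple[pd.DataFrame, int]:
    """Drop every row of any patient with an unknown model covariate.

    Returns the filtered table and the number of excluded patients.
    """
    bad = pd.Series(False, index=table.index)
    for c in covariates:
        if c in table.columns and table[c].dtype == object:
            bad |= table[c] == UNKNOWN
    bad_ids = set(table.loc[bad, "id"])
    kept = table[~table["id"].isin(bad_ids)]
    return kept, len(bad_ids)


def _design(sub: pd.DataFrame, covariates):
    """Dummy-encode covariates against their reference levels."""
    cols, names = [], []
    for c in covariates:
        v = sub[c]
        if np.issubdtype(v.dtype, np.number):
            cols.append(v.to_numpy(float))
            names.append(c)
            continue
        ref = REFERENCE_LEVELS.get(c)
        order = LEVEL_ORDER.get(c)
        present = list(pd.unique(v))
        levels = [l for l in (order or sorted(present)) if l in present and l != ref]
        extra = [l for l in present if order and l not in order and l != UNKNOWN]
        for lvl in levels + sorted(extra):
            cols.append((v == lvl).to_numpy(float))
            names.append(f"{c}:{lvl}")
    X = np.column_stack(cols) if cols else np.empty((len(sub), 0))
    return X, names


def _check_aliased(X, names):
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise CollinearDesignError(name)
    if X.shape[1] > 1:
        Xc = X - X.mean(axis=0)
        rank = np.linalg.matrix_rank(Xc)
        if rank < X.shape[1]:
            # name the last column whose removal restores full rank
            for j in range(X.shape[1] - 1, -1, -1):
                sub = np.delete(Xc, j, axis=1)
                if np.linalg.matrix_rank(sub) == sub.shape[1]:
                    raise CollinearDesignError(names[j])
            raise CollinearDesignError(names[-1])


def _partial_loglik(beta, start, stop, event, X, ties):
    """Log partial likelihood, gradient and Hessian (negative definite)."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(stop[event]):
        at_risk = (start < t) & (t <= stop)
        dead = at_risk & event & (stop == t)
        wr = w[at_risk]
        Xr = X[at_risk]
        S0 = wr.sum()
        S1 = wr @ Xr
        S2 = (wr[:, None] * Xr).T @ Xr
        wd = w[dead]
        Xd = X[dead]
        d = len(wd)
        ll += eta[dead].sum()
        if ties == "breslow" or d == 1:
            ll -= d * np.log(S0)
            grad += Xd.sum(axis=0) - d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1 / S0, S1 / S0))
        elif ties == "efron":
            S0d = wd.sum()
            S1d = wd @ Xd
            S2d = (wd[:, None] * Xd).T @ Xd
            for m in range(d):
                f = m / d
                phi = S0 - f * S0d
                psi = (S1 - f * S1d) / phi
                ll -= np.log(phi)
                grad -= psi
                hess -= (S2 - f * S2d) / phi - np.outer(psi, psi)
            grad += Xd.sum(axis=0)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return ll, grad, hess


def _newton(start, stop, event, X, ties, tol=1e-9, max_iter=50):
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _partial_loglik(beta, start, stop, event, X, ties)
    if p == 0:  # null model: the partial likelihood has no parameters
        return beta, ll, grad, hess, True, False
    converged, monotone = False, False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            monotone = True
            break
        new_beta = beta + step
        new = _partial_loglik(new_beta, start, stop, event, X, ties)
        halvings = 0
        while new[0] < ll and halvings < 20:  # step-halving on overshoot
            step /= 2.0
            new_beta = beta + step
            new = _partial_loglik(new_beta, start, stop, event, X, ties)
            halvings += 1
        beta = new_beta
        delta = new[0] - ll
        ll, grad, hess = new
        if np.abs(beta).max() > 15:
            monotone = True
            break
        if abs(delta) < tol * (abs(ll) + 1e-8):
            converged = True
            break
    if monotone:
        warnings.warn(
            "monotone partial likelihood: an estimate diverges; "
            "interpret the flagged coefficients as unbounded",
            MonotoneLikelihoodWarning,
        )
    return beta, ll, grad, hess, converged, monotone


class CoxTransitionModel:
    """Cox proportional-hazards model for one transition of the state graph.

    Parameters
    ----------
    table : DataFrame
        Long-format transition data (all transitions); rows for the
        requested transition are selected internally.
    transition : tuple or int
        ``(from_state, to_state)`` labels or an mstate-style transition number.
    covariates : sequence of str
        Covariate columns; categorical columns are dummy-coded against
        :data:`REFERENCE_LEVELS`.
    ties : str
        'efron' (default) or 'breslow'.
    """

    def __init__(self, table, transition, covariates, ties: str = "efron", graph=None):
        if isinstance(transition, int):
            if graph is None:
                raise ValueError("transition number requires the graph")
            transition = graph.transitions[transition - 1]
        self.transition = tuple(transition)
        self.covariates = tuple(covariates)
        self.ties = ties
        sub = table[
            (table["from"] == self.transition[0]) & (table["to"] == self.transition[1])
        ]
        if not len(sub):
            raise ValueError(f"no at-risk rows for transition {self.transition}")
        self.data, self.n_excluded = complete_cases(sub, self.covariates)
        if not self.data["status"].sum():
            raise ValueError(f"zero events for transition {self.transition}")

    def fit(self) -> "CoxTransitionResults":
        sub = self.data
        X, names = _design(sub, self.covariates)
        _check_aliased(X, names)
        start = sub["Tstart"].to_numpy(float)
        stop = sub["Tstop"].to_numpy(float)
        event = sub["status"].to_numpy(int).astype(bool)
        beta, ll, grad, hess, converged, monotone = _newton(
            start, stop, event, X, self.ties
        )
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.full((len(beta), len(beta)), np.nan)
        return CoxTransitionResults(
            model=self,
            term_names=names,
            params=pd.Series(beta, index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            loglik=ll,
            converged=converged,
            monotone=monotone,
            nobs=sub["id"].nunique(),
            n_events=int(event.sum()),
            _arrays=(start, stop, event, X),
        )


@dataclass
class CoxTransitionResults:
    """Estimates, Wald inference and baseline hazard for one transition."""

    model: CoxTransitionModel
    term_names: list[str]
    params: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    converged: bool
    monotone: bool
    nobs: int
    n_events: int
    _arrays: tuple = field(repr=False, default=None)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.term_names)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.term_names)

    def baseline_cumulative_hazard(self) -> pd.DataFrame:
        """Breslow baseline H0(t) at the reference covariate pattern."""
        start, stop, event, X = self._arrays
        w = np.exp(X @ self.params.to_numpy())
        times = np.unique(stop[event])
        inc = np.empty(len(times))
        for i, t in enumerate(times):
            at_risk = (start < t) & (t <= stop)
            d = np.sum(event & (stop == t))
            inc[i] = d / w[at_risk].sum()
        return pd.DataFrame({"time": times, "cumhaz": np.cumsum(inc), "increment": inc})

    def linear_predictor(self, pattern: dict) -> float:
        """x'beta for a covariate pattern given as {covariate: level/value}."""
        x = np.zeros(len(self.term_names))
        for j, name in enumerate(self.term_names):
            if ":" in name:
                cov, lvl = name.split(":", 1)
                if cov not in pattern:
                    raise KeyError(f"pattern missing covariate {cov!r}")
                if pattern[cov] == lvl:
                    x[j] = 1.0
            else:
                x[j] = float(pattern[name])
        known = {n.split(":", 1)[0] for n in self.term_names}
        for cov, lvl in pattern.items():
            if cov in known and isinstance(lvl, str):
                seen = {n.split(":", 1)[1] for n in self.term_names if n.startswith(cov + ":")}
                if lvl not in seen and lvl != REFERENCE_LEVELS.get(cov):
                    warnings.warn(
                        f"level {lvl!r} of {cov!r} unseen in training data; "
                        "treated as the reference level (extrapolation)"
                    )
        return float(x @ self.params.to_numpy())

    def predicted_cumhaz(self, pattern: dict) -> pd.DataFrame:
        base = self.baseline_cumulative_hazard()
        hr = np.exp(self.linear_predictor(pattern))
        out = base.copy()
        out["cumhaz"] *= hr
        out["increment"] *= hr
        return out

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "term": self.term_names,
                "coef": self.params.to_numpy(),
                "HR": self.hazard_ratios.to_numpy(),
                "lower": ci["lower"].to_numpy(),
                "upper": ci["upper"].to_numpy(),
                "se": self.bse.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )

    def __str__(self) -> str:
        head = (
            f"Cox PH transition {self.model.transition[0]} -> "
            f"{self.model.transition[1]} (ties={self.model.ties})\n"
            f"n={self.nobs} patients ({self.model.n_excluded} excluded, "
            f"incomplete cases), events={self.n_events}, "
            f"loglik={self.loglik:.4f}, converged={self.converged}"
        )
        if self.monotone:
            head += "\nWARNING: monotone likelihood — estimates unbounded"
        return head + "\n" + self.summary().to_string(index=False)


def fit_cox(table, transition, covariates, ties="efron", graph=None) -> CoxTransitionResults:
    """Functional wrapper: build and fit a :class:`CoxTransitionModel`."""
    return CoxTransitionModel(table, transition, covariates, ties, graph).fit()
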