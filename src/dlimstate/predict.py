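"""Semi-parametric multi-state prediction for reference patients.

Transition-specific Cox fits are integrated as components of the Markov
multi-state model: for an "equipped" transition the pattern-specific
cumulative hazard is A_jk(t | x) = H0_jk(t) exp(x'beta_jk); the remaining
transitions keep their Nelson–Aalen estimates.  Product-integration of the
combined hazard increments gives patient-specific state-occupation
probabilities and composite endpoints (the reference-patient prediction
machinery).  Confidence bands come from a patient-level bootstrap that
refits every Cox component inside each resample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxTransitionModel, CoxTransitionResults
from .graph import StateGraph
from .nonparametric import (
    COMPOSITE_ORDER,
    HazardEstimate,
    ProbabilityMatrix,
    _step_eval,
    composite_curves,
    nelson_aalen,
)

__all__ = ["SemiParametricMSM", "MSMPrediction", "assemble_model", "predict_patient"]


@dataclass
class SemiParametricMSM:
    """A multi-state model with Cox-equipped and nonparametric transitions."""

    graph: StateGraph
    fits: dict[tuple[str, str], CoxTransitionResults]
    fallback: HazardEstimate

    def __post_init__(self):
        allowed = set(self.graph.transitions)
        for t in self.fits:
            if tuple(t) not in allowed:
                raise ValueError(f"equipped transition {t} absent from graph")
        if self.fallback.graph.transitions != self.graph.transitions:
            raise ValueError("fallback hazards were estimated on a different graph")

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        graph: StateGraph,
        equipped: dict[tuple[str, str], tuple[str, ...]],
        ties: str = "efron",
    ) -> "SemiParametricMSM":
        """Fit Cox models for ``equipped`` ({transition: covariates}) and
        Nelson–Aalen hazards for everything else."""
        fits = {
            tuple(t): CoxTransitionModel(table, t, covs, ties).fit()
            for t, covs in equipped.items()
        }
        return cls(graph, fits, nelson_aalen(table, graph))

    @property
    def equipped(self) -> tuple[tuple[str, str], ...]:
        return tuple(self.fits)

    def predict(self, pattern: dict, s: float = 0.0) -> "MSMPrediction":
        """State-occupation probabilities for a reference covariate pattern."""
        g = self.graph
        inc: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for k, (a, b) in enumerate(g.transitions):
            if (a, b) in self.fits:
                ch = self.fits[(a, b)].predicted_cumhaz(pattern)
                inc[(a, b)] = (ch["time"].to_numpy(), ch["increment"].to_numpy())
            else:
                dA = self.fallback.dA[k]
                nz = dA > 0
                inc[(a, b)] = (self.fallback.times[nz], dA[nz])
        # a discrete hazard increment cannot exceed 1; pattern-specific
        # scaling can push tail increments (risk set ~1) beyond it
        clipped = False
        for key, (tt, dd) in inc.items():
            if len(dd) and dd.max() > 1.0:
                inc[key] = (tt, np.minimum(dd, 1.0))
                clipped = True
        if clipped:
            warnings.warn(
                "pattern-specific hazard increments above 1 were truncated "
                "(sparse tail risk sets); tail probabilities are extrapolations"
            )

        times = np.unique(np.concatenate([t for t, _ in inc.values()] or [np.array([])]))
        times = times[times > s]
        n = g.n_states
        P = np.empty((len(times) + 1, n, n))
        P[0] = np.eye(n)
        cur = np.eye(n)
        for i, u in enumerate(times, start=1):
            M = np.eye(n)
            for (a, b), (tt, dd) in inc.items():
                j = np.searchsorted(tt, u)
                if j < len(tt) and tt[j] == u:
                    d = dd[j]
                    ia, ib = g.index(a), g.index(b)
                    M[ia, ib] += d
                    M[ia, ia] -= d
            if np.diag(M).min() < 0:
                warnings.warn(
                    f"total hazard increment above 1 at t={u}: the predicted "
                    "pattern is an extreme extrapolation"
                )
            cur = cur @ M
            P[i] = cur
        pm = ProbabilityMatrix(g, s, np.concatenate([[s], times]), P)
        return MSMPrediction(self, pattern, pm)


@dataclass
class MSMPrediction:
    model: SemiParametricMSM
    pattern: dict
    probabilities: ProbabilityMatrix

    def occupation(self, start=None) -> pd.DataFrame:
        return self.probabilities.occupation(start)

    def composites(self, start=None) -> pd.DataFrame:
        return composite_curves(self.probabilities, start)

    def summary(self, horizons=(182.625, 365.25), start=None) -> str:
        comp = self.composites(start)
        lines = [
            "Semi-parametric multi-state prediction",
            "  pattern: " + ", ".join(f"{k}={v}" for k, v in self.pattern.items()),
            "  equipped transitions: "
            + "; ".join(f"{a}->{b}" for a, b in self.model.equipped),
            f"  {'endpoint':<16}" + "".join(f"{h / 30.4375:>10.0f} mo" for h in horizons),
        ]
        for ep, grp in comp.groupby("endpoint", sort=False):
            vals = _step_eval(
                grp["time"].to_numpy(), grp["estimate"].to_numpy(),
                np.asarray(horizons, float), grp["estimate"].iloc[0],
            )
            lines.append(f"  {ep:<16}" + "".join(f"{v:>11.3f} " for v in vals))
        return "\n".join(lines)


def assemble_model(graph, fits, fallback) -> SemiParametricMSM:
    """Functional wrapper for :class:`SemiParametricMSM`."""
    return SemiParametricMSM(graph, {tuple(k): v for k, v in fits.items()}, fallback)


def predict_patient(model: SemiParametricMSM, pattern: dict, s: float = 0.0):
    """Predict occupation probabilities and composites for one pattern."""
    pred = model.predict(pattern, s=s)
    return pred.probabilities, pred.composites()


def bootstrap_prediction_bands(
    table: pd.DataFrame,
    graph: StateGraph,
    equipped: dict[tuple[str, str], tuple[str, ...]],
    pattern: dict,
    seed: int,
    B: int = 200,
    level: float = 0.95,
    ties: str = "efron",
    endpoints: tuple[str, ...] = COMPOSITE_ORDER,
    start=None,
) -> pd.DataFrame:
    """Percentile bands for predicted composites, refitting inside resamples."""
    rng = np.random.default_rng(seed)
    base = SemiParametricMSM.from_table(table, graph, equipped, ties)
    est = base.predict(pattern).composites(start)
    ids = table["id"].unique()
    groups = {i: g for i, g in table.groupby("id", sort=False)}
    grids = {ep: g["time"].to_numpy() for ep, g in est.groupby("endpoint")}
    draws = {ep: np.empty((B, len(g))) for ep, g in grids.items()}
    for b in range(B):
        sample = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for k, pid in enumerate(sample):
            g = groups[pid].copy()
            g["id"] = f"b{k}"
            parts.append(g)
        bt = pd.concat(parts, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bc = (
                SemiParametricMSM.from_table(bt, graph, equipped, ties)
                .predict(pattern)
                .composites(start)
            )
        for ep, g in bc.groupby("endpoint"):
            draws[ep][b] = _step_eval(
                g["time"].to_numpy(), g["estimate"].to_numpy(), grids[ep],
                g["estimate"].iloc[0],
            )
    alpha = 1.0 - level
    lo, hi = [], []
    for _, row in est.iterrows():
        ep = row["endpoint"]
        j = np.searchsorted(grids[ep], row["time"])
        lo.append(np.quantile(draws[ep][:, j], alpha / 2))
        hi.append(np.quantile(draws[ep][:, j], 1 - alpha / 2))
    out = est.copy()
    out["lower"], out["upper"] = lo, hi
    return out
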