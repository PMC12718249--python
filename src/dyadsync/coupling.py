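"""Per-dyad RSA synchrony as a baseline-referenced coupled autoregression.

For dyad i with task epochs t = 1..T (child C, mother M) and baseline
reference values C_base, M_base:

    C_t - C_base = a_i (C_{t-1} - C_base) + s_i (M_t - M_base) + eps_t

The concurrent mother->child slope s_i is the dyad's RSA synchrony; a_i
absorbs the autoregression of child RSA.  Two estimators:

* ``per_dyad_ols`` — transparent least squares within each dyad;
* ``hierarchical_map`` — empirical-Bayes partial pooling: per-dyad OLS slopes
  are shrunk toward a group mean mu_s under a normal prior whose scale tau_s
  is estimated by marginal likelihood, yielding maximum-a-posteriori
  per-dyad slopes.  Shrinkage never moves a slope past the group mean.

A lag-1 mother term can replace the concurrent one (``mother_lag=1``) since
the original lag convention is ambiguous in this literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


@dataclass
class CouplingModelSpec:
    estimator: str = "per_dyad_ols"      # or "hierarchical_map"
    mother_lag: int = 0                  # 0 = concurrent (default), 1 = lagged
    direction: str = "mother_to_child"   # or "child_to_mother" (exposed, unused
    #                                      by default: synchrony moderates the
    #                                      child outcome)
    prior_scale_slope: float | None = None  # fix tau_s instead of estimating
    max_iter: int = 200
    tolerance: float = 1e-8

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.estimator not in ("per_dyad_ols", "hierarchical_map"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.mother_lag not in (0, 1):
            raise ValueError("mother_lag must be 0 or 1")
        if self.direction not in ("mother_to_child", "child_to_mother"):
            raise ValueError(f"unknown direction {self.direction!r}")


class DyadicCouplingModel:
    """Dyad-level coupling model over epoch-mean RSA series.

    Parameters
    ----------
    dyads : mapping dyad_id -> dict with keys ``mother_epochs``,
        ``child_epochs`` (equal-length arrays of epoch-mean RSA),
        ``mother_baseline``, ``child_baseline`` (scalars).
    """

    def __init__(self, dyads: dict, spec: CouplingModelSpec | None = None):
        self.spec = spec or CouplingModelSpec()
        self.dyads = dict(dyads)
        for did, d in self.dyads.items():
            m, c = np.asarray(d["mother_epochs"], float), np.asarray(d["child_epochs"], float)
            if len(m) != len(c):
                raise ValueError(f"dyad {did}: partner epoch counts differ")
            if len(c) < 3:
                raise ValueError(f"dyad {did}: need >= 3 epochs")
            if not (np.isfinite(d["mother_baseline"]) and np.isfinite(d["child_baseline"])):
                raise ValueError(f"dyad {did}: baselines must be finite")

    @classmethod
    def from_dataframe(cls, epochs: pd.DataFrame, baselines: pd.DataFrame,
                       spec: CouplingModelSpec | None = None) -> "DyadicCouplingModel":
        """Build from long-format tables.

        ``epochs``: columns (dyad_id, epoch, mother_rsa, child_rsa);
        ``baselines``: columns (dyad_id, mother_baseline, child_baseline).
        """
        base = baselines.set_index("dyad_id")
        dyads = {}
        for did, grp in epochs.sort_values("epoch").groupby("dyad_id"):
            dyads[did] = dict(mother_epochs=grp["mother_rsa"].to_numpy(),
                              child_epochs=grp["child_rsa"].to_numpy(),
                              mother_baseline=float(base.loc[did, "mother_baseline"]),
                              child_baseline=float(base.loc[did, "child_baseline"]))
        return cls(dyads, spec)

    def _design(self, d) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(d["child_epochs"], float) - d["child_baseline"]
        m = np.asarray(d["mother_epochs"], float) - d["mother_baseline"]
        if self.spec.direction == "child_to_mother":
            c, m = m, c
        y = c[1:]
        lag = c[:-1]
        mom = m[1:] if self.spec.mother_lag == 0 else m[:-1]
        return np.column_stack([lag, mom]), y

    def fit(self) -> "CouplingResults":
        rows, excluded = [], []
        for did, d in self.dyads.items():
            X, y = self._design(d)
            if np.linalg.matrix_rank(X) < 2:
                excluded.append((did, "rank-deficient design (constant partner series)"))
                continue
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = len(y) - 2
            if dof > 0:
                resid = y - X @ beta
                sigma2 = float(resid @ resid) / dof
                cov = sigma2 * np.linalg.inv(X.T @ X)
                se_a, se_s = np.sqrt(np.diag(cov))
            else:
                se_a = se_s = np.nan
            rows.append(dict(dyad_id=did, ar=float(beta[0]), slope=float(beta[1]),
                             se=float(se_s), se_ar=float(se_a)))
        if not rows:
            raise ValueError("no dyad produced a full-rank design")
        table = pd.DataFrame(rows)

        if self.spec.estimator == "hierarchical_map":
            table, mu, tau = self._shrink(table)
        else:
            mu = float(table["slope"].mean())
            tau = float(table["slope"].std(ddof=1)) if len(table) > 1 else 0.0
        return CouplingResults(per_dyad=table, mu_s=mu, tau_s=tau,
                               n_dyads_used=len(table), exclusions=excluded,
                               spec=self.spec)

    def _shrink(self, table: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
        """Normal-normal empirical Bayes on the per-dyad OLS slopes."""
        s = table["slope"].to_numpy()
        se2 = np.clip(table["se"].to_numpy() ** 2, 1e-12, None)

        def neg_marginal(log_tau):
            tau2 = np.exp(log_tau) ** 2
            w = 1.0 / (se2 + tau2)
            mu = np.sum(w * s) / np.sum(w)
            return -0.5 * np.sum(np.log(w)) + 0.5 * np.sum(w * (s - mu) ** 2)

        if self.spec.prior_scale_slope is not None:
            tau = float(self.spec.prior_scale_slope)
        else:
            opt = minimize_scalar(neg_marginal, bounds=(np.log(1e-6), np.log(10.0)),
                                  method="bounded",
                                  options={"xatol": self.spec.tolerance,
                                           "maxiter": self.spec.max_iter})
            tau = float(np.exp(opt.x))
        w = 1.0 / (se2 + tau ** 2)
        mu = float(np.sum(w * s) / np.sum(w))
        post = (s / se2 + mu / tau ** 2) / (1.0 / se2 + 1.0 / tau ** 2)
        post_se = np.sqrt(1.0 / (1.0 / se2 + 1.0 / tau ** 2))
        table = table.assign(slope_ols=s, slope=post, se_ols=np.sqrt(se2), se=post_se)
        return table, mu, tau


@dataclass
class CouplingResults:
    """Fitted dyadic coupling: per-dyad slopes, group summaries, exclusions."""

    per_dyad: pd.DataFrame
    mu_s: float
    tau_s: float
    n_dyads_used: int
    exclusions: list
    spec: CouplingModelSpec

    def synchrony(self) -> pd.Series:
        """Per-dyad synchrony s_i, indexed by dyad_id."""
        return self.per_dyad.set_index("dyad_id")["slope"]

    def summary(self) -> str:
        lines = [
            "Dyadic RSA coupling model",
            f"  estimator        : {self.spec.estimator}",
            f"  mother term      : {'concurrent' if self.spec.mother_lag == 0 else 'lag-1'}",
            f"  dyads used       : {self.n_dyads_used} "
            f"({len(self.exclusions)} excluded)",
            f"  group mean mu_s  : {self.mu_s: .4f}",
            f"  group scale tau_s: {self.tau_s: .4f}",
        ]
        for did, why in self.exclusions:
            lines.append(f"  excluded {did}: {why}")
        return "\n".join(lines)
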