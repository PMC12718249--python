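"""Moderation models, Johnson-Neyman probing, descriptives, and the
random-pairing permutation control.

The moderation design regresses child dysregulation on a grand-mean-centered
focal predictor (maternal positive or negative affect), a centered dyad-level
synchrony moderator, their product, and covariates (the other affect scale,
child gender, income), by OLS.  Standardized betas use the analyzed-sample
SDs after listwise deletion.  Significant interactions are probed with the
Johnson-Neyman technique: the simple slope theta(m) = B_iv + B_int * m is
significant where theta(m)^2 > t_crit^2 * Var(theta(m)), with the boundaries
the real roots of the corresponding quadratic.

The permutation control re-pairs each mother with a random child from
another dyad (a uniformly sampled derangement, so no mother keeps her own
child and each child appears exactly once per permutation), averages the
resulting pseudo coherence per mother, and refits the moderation models with
the pseudo values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats

from .wtc import WaveletSpec, coherence_matrix, DEFAULT_FOI


def mean_center(values) -> np.ndarray:
    """Subtract the grand mean of the finite entries (NaNs propagate)."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values to center")
    return x - x[finite].mean()


@dataclass
class ModerationSpec:
    outcome: str = "dysregulation"
    iv: str = "pa"
    moderator: str = "rsa_sync"
    covariates: tuple = ("na", "gender", "income")
    alpha: float = 0.05

    def __post_init__(self):
        if self.iv in self.covariates:
            raise ValueError("the focal predictor cannot also be a covariate")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


class ModerationModel:
    """OLS moderation model with an iv x moderator interaction.

    Built from a behavioral DataFrame; `fit()` returns a
    :class:`ModerationResults` carrying coefficients, standardized betas, the
    coefficient covariance (for Johnson-Neyman probing), and model fit
    statistics.
    """

    def __init__(self, table: pd.DataFrame, spec: ModerationSpec):
        self.spec = spec
        cols = [spec.outcome, spec.iv, spec.moderator, *spec.covariates]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise KeyError(f"table lacks columns {missing}")
        data = table[cols].apply(pd.to_numeric).dropna()  # listwise deletion
        n_predictors = 3 + len(spec.covariates)
        if len(data) < n_predictors + 2:
            raise ValueError("too few complete cases for the design")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, iv: str = "pa",
                       moderator: str = "rsa_sync",
                       outcome: str = "dysregulation",
                       covariates: tuple | None = None,
                       alpha: float = 0.05) -> "ModerationModel":
        if covariates is None:
            covariates = ("na" if iv == "pa" else "pa", "gender", "income")
        return cls(table, ModerationSpec(outcome=outcome, iv=iv, moderator=moderator,
                                         covariates=covariates, alpha=alpha))

    def fit(self) -> "ModerationResults":
        s = self.spec
        d = self.data
        iv_c = mean_center(d[s.iv])
        mod_c = mean_center(d[s.moderator])
        X = pd.DataFrame({s.iv: iv_c, s.moderator: mod_c,
                          f"{s.iv}_x_{s.moderator}": iv_c * mod_c})
        for cov in s.covariates:
            X[cov] = d[cov].to_numpy()
        Xc = sm.add_constant(X, prepend=True)
        rank = np.linalg.matrix_rank(Xc.to_numpy())
        if rank < Xc.shape[1]:
            corr = X.corr().abs()
            np.fill_diagonal(corr.values, 0)
            worst = corr.stack().idxmax()
            raise ValueError(f"singular design; near-collinear terms {worst}")
        res = sm.OLS(d[s.outcome].to_numpy(), Xc).fit()
        sd_y = d[s.outcome].std(ddof=1)
        betas = {}
        for term in X.columns:
            betas[term] = res.params[term] * X[term].std(ddof=1) / sd_y
        table = pd.DataFrame({
            "B": res.params, "SE": res.bse, "t": res.tvalues, "p": res.pvalues,
        })
        table["beta"] = pd.Series(betas)  # NaN for the intercept
        return ModerationResults(
            spec=s, params=table, r_squared=float(res.rsquared),
            f_stat=float(res.fvalue), f_df=(int(res.df_model), int(res.df_resid)),
            f_pvalue=float(res.f_pvalue), n=int(res.nobs),
            cov_params=res.cov_params(),
            moderator_range=(float(mod_c.min()), float(mod_c.max())),
            moderator_mean=float(d[s.moderator].mean()),
        )


@dataclass
class ModerationResults:
    """Fitted moderation model in the layout of a B / SE / beta / p table."""

    spec: ModerationSpec
    params: pd.DataFrame
    r_squared: float
    f_stat: float
    f_df: tuple
    f_pvalue: float
    n: int
    cov_params: pd.DataFrame
    moderator_range: tuple
    moderator_mean: float

    @property
    def interaction_term(self) -> str:
        return f"{self.spec.iv}_x_{self.spec.moderator}"

    @property
    def interaction_p(self) -> float:
        return float(self.params.loc[self.interaction_term, "p"])

    @property
    def interaction_b(self) -> float:
        return float(self.params.loc[self.interaction_term, "B"])

    def summary(self) -> str:
        s = self.spec
        head = (f"Moderation: {s.outcome} ~ {s.iv} * {s.moderator} "
                f"+ {' + '.join(s.covariates)}\n"
                f"n = {self.n}   R^2 = {self.r_squared:.3f}   "
                f"F({self.f_df[0]}, {self.f_df[1]}) = {self.f_stat:.2f}, "
                f"p = {self.f_pvalue:.4f}")
        tab = self.params[["B", "SE", "beta", "p"]].round(4).to_string()
        return head + "\n" + tab

    def johnson_neyman(self) -> "JnRegions":
        return johnson_neyman(self, self.spec)

    def simple_slope(self, m_centered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """theta(m) and its SE on the centered moderator scale."""
        b1 = self.params.loc[self.spec.iv, "B"]
        b3 = self.params.loc[self.interaction_term, "B"]
        v11 = self.cov_params.loc[self.spec.iv, self.spec.iv]
        v13 = self.cov_params.loc[self.spec.iv, self.interaction_term]
        v33 = self.cov_params.loc[self.interaction_term, self.interaction_term]
        m = np.asarray(m_centered, dtype=float)
        theta = b1 + b3 * m
        var = v11 + 2 * m * v13 + m ** 2 * v33
        return theta, np.sqrt(np.maximum(var, 0.0))


@dataclass
class JnRegions:
    """Johnson-Neyman regions of significance on the centered moderator scale."""

    boundaries: list            # 0, 1, or 2 moderator values, ascending
    regions: list               # dicts: interval, slope_sign, significant
    alpha: float
    df: int
    observed_range: tuple
    boundaries_in_range: list = field(default_factory=list)

    def describe(self) -> str:
        parts = [f"J-N boundaries (centered moderator): "
                 f"{', '.join(f'{b:.4f}' for b in self.boundaries) or 'none'}"]
        for r in self.regions:
            a, b = r["interval"]
            parts.append(f"  ({a:.4g}, {b:.4g}): slope {r['slope_sign']}, "
                         f"{'significant' if r['significant'] else 'ns'}")
        return "\n".join(parts)


def johnson_neyman(result: ModerationResults, spec: ModerationSpec | None = None
                   ) -> JnRegions:
    """Closed-form J-N boundaries for the iv simple slope across the moderator.

    Solves theta(m)^2 = t_crit^2 Var(theta(m)), a quadratic in m with
    a = B3^2 - t^2 V33, b = 2 (B1 B3 - t^2 V13), c = B1^2 - t^2 V11.
    Regions partition the moderator axis and are labeled with the sign and
    significance of the slope at their midpoint; boundaries outside the
    observed (centered) moderator range are flagged.
    """
    spec = spec or result.spec
    alpha = spec.alpha
    df = result.f_df[1]
    t_crit = spstats.t.ppf(1 - alpha / 2, df)
    b1 = result.params.loc[spec.iv, "B"]
    b3 = result.params.loc[result.interaction_term, "B"]
    v11 = result.cov_params.loc[spec.iv, spec.iv]
    v13 = result.cov_params.loc[spec.iv, result.interaction_term]
    v33 = result.cov_params.loc[result.interaction_term, result.interaction_term]

    if v33 <= 0:
        theta, se = result.simple_slope(np.array([0.0]))
        sig = bool(abs(theta[0]) > t_crit * se[0]) if se[0] > 0 else True
        region = dict(interval=(-np.inf, np.inf),
                      slope_sign="+" if theta[0] >= 0 else "-", significant=sig)
        return JnRegions([], [region], alpha, df, result.moderator_range)

    a = b3 ** 2 - t_crit ** 2 * v33
    b = 2 * (b1 * b3 - t_crit ** 2 * v13)
    c = b1 ** 2 - t_crit ** 2 * v11
    roots = []
    if abs(a) < 1e-300:
        if abs(b) > 0:
            roots = [-c / b]
    else:
        disc = b ** 2 - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = sorted([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    edges = [-np.inf, *roots, np.inf]
    lo, hi = result.moderator_range
    regions = []
    for left, right in zip(edges[:-1], edges[1:]):
        mid_lo = left if np.isfinite(left) else min(lo, right - 1.0)
        mid_hi = right if np.isfinite(right) else max(hi, left + 1.0)
        mid = 0.5 * (mid_lo + mid_hi)
        theta, se = result.simple_slope(np.array([mid]))
        sig = bool(abs(theta[0]) > t_crit * se[0])
        regions.append(dict(interval=(left, right),
                            slope_sign="+" if theta[0] >= 0 else "-",
                            significant=sig))
    in_range = [bool(lo <= r <= hi) for r in roots]
    return JnRegions(list(roots), regions, alpha, df, result.moderator_range, in_range)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (FDR), offered as an optional extension.

    The primary analysis reports the ten moderation models uncorrected,
    matching the design it mirrors; apply this to their interaction p-values
    when a false-discovery-rate guarantee across models is wanted.
    """
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def correlation_table(table: pd.DataFrame, star_levels=(0.05, 0.01)
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptives (mean, SD) and pairwise-complete Pearson correlations.

    Returns (descriptives, matrix) where the matrix holds strings like
    '-0.26*'; zero-variance variables yield blank (undefined) entries.
    """
    num = table.select_dtypes("number")
    desc = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
    cols = num.columns
    mat = pd.DataFrame("", index=cols, columns=cols)
    for i, ci in enumerate(cols):
        mat.loc[ci, ci] = "1"
        for cj in cols[i + 1:]:
            sub = num[[ci, cj]].dropna()
            if len(sub) < 3 or sub[ci].std() == 0 or sub[cj].std() == 0:
                continue
            r, p = spstats.pearsonr(sub[ci], sub[cj])
            stars = "**" if p < star_levels[1] else ("*" if p < star_levels[0] else "")
            mat.loc[cj, ci] = f"{r:.2f}{stars}"
    return desc, mat


def random_pairings(dyad_ids: list, n_permutations: int = 100,
                    seed: int | np.random.Generator = 0) -> "PairingScheme":
    """Uniformly sampled derangements of the dyads.

    Each permutation maps every mother to a random child from *another* dyad
    (a bijection with no fixed points), by rejection sampling, which is
    uniform over derangements.
    """
    ids = list(dyad_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need >= 3 dyads for a meaningful permutation control")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = []
    while len(perms) < n_permutations:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            perms.append(p)
    return PairingScheme(dyad_ids=ids, permutations=np.asarray(perms))


@dataclass
class PairingScheme:
    dyad_ids: list
    permutations: np.ndarray    # (n_permutations, n_dyads) of child indices

    @property
    def n_permutations(self) -> int:
        return self.permutations.shape[0]

    def __post_init__(self):
        n = len(self.dyad_ids)
        for p in self.permutations:
            if sorted(p) != list(range(n)):
                raise ValueError("each permutation must be a bijection")
            if np.any(p == np.arange(n)):
                raise ValueError("permutations must have no fixed points")


def permuted_coherence(mother_signals: dict, child_signals: dict,
                       scheme: PairingScheme, dt: float = 1.0,
                       spec: WaveletSpec | None = None,
                       foi: tuple = DEFAULT_FOI, coi_policy: str = "exclude"
                       ) -> pd.Series:
    """Mean pseudo-pair FOI coherence per mother across all permutations.

    ``mother_signals``/``child_signals`` map dyad_id -> 1-D array (one region
    and chromophore at a time).  Signals of unequal length are truncated to
    the common length.  Unique mother-child pairs are computed once and
    averaged per the pairing scheme.
    """
    ids = scheme.dyad_ids
    n_min = min(min(len(v) for v in mother_signals.values()),
                min(len(v) for v in child_signals.values()))
    xs = [np.asarray(mother_signals[i], float)[:n_min] for i in ids]
    ys = [np.asarray(child_signals[i], float)[:n_min] for i in ids]
    pairs = sorted({(i, int(j)) for p in scheme.permutations for i, j in enumerate(p)})
    mat = coherence_matrix(xs, ys, dt, spec, foi, coi_policy, pairs=pairs)
    out = np.zeros(len(ids))
    for p in scheme.permutations:
        out += mat[np.arange(len(ids)), p]
    return pd.Series(out / scheme.n_permutations, index=ids, name="pseudo_coherence")


def permutation_check(behavior: pd.DataFrame, pseudo: pd.Series,
                      iv: str = "pa", moderator_name: str = "pseudo_coherence",
                      alpha: float = 0.05) -> ModerationResults:
    """Refit a moderation model with pseudo-pair synchrony as the moderator."""
    table = behavior.set_index("dyad_id").join(pseudo.rename(moderator_name))
    table = table.reset_index()
    model = ModerationModel.from_dataframe(table, iv=iv, moderator=moderator_name,
                                           alpha=alpha)
    return model.fit()
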