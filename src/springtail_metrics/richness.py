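"""Sample-based rarefaction, Chao richness extrapolation, and the
sampling-completeness model.

Unequal sampling effort across sites is handled by (i) analytic sample-based
rarefaction, (ii) the incidence-based Chao estimator with the (m-1)/m
small-sample correction, and (iii) a binomial GLM of completeness
(observed / extrapolated richness) on the number of samples and latitude,
used to back-correct observed richness at sites where only pooled species
lists are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.families.family import Binomial
from statsmodels.tools.sm_exceptions import DomainWarning, PerfectSeparationError


class IncidenceMatrix:
    """Binary samples x species incidence matrix for one site."""

    def __init__(self, incidence) -> None:
        arr = np.asarray(incidence)
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("incidence must be a 2-D samples x species matrix")
        self.matrix = arr > 0

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, taxon_col: str = "taxon") -> "IncidenceMatrix":
        """Build from one site's long-format sample x taxon abundance rows."""
        pivot = samples.pivot_table(
            index="sample_id", columns=taxon_col, values="abundance",
            aggfunc="sum", fill_value=0,
        )
        return cls(pivot.to_numpy())

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def incidence_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def s_obs(self) -> int:
        return int((self.incidence_counts > 0).sum())

    @property
    def q1(self) -> int:
        return int((self.incidence_counts == 1).sum())

    @property
    def q2(self) -> int:
        return int((self.incidence_counts == 2).sum())


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_curve(inc: IncidenceMatrix) -> np.ndarray:
    """Expected species count at t = 1..m pooled samples (hypergeometric).

    E[S(t)] = sum_i [1 - C(m - m_i, t) / C(m, t)] with m_i the number of
    samples containing species i; exact, non-decreasing, equals S_obs at t=m.
    """
    m = inc.m
    mi = inc.incidence_counts[inc.incidence_counts > 0]
    t = np.arange(1, m + 1)
    # C(m - mi, t) / C(m, t), zero when t > m - mi
    curve = np.empty(m, dtype=float)
    for j, tt in enumerate(t):
        valid = (m - mi) >= tt
        frac = np.zeros(mi.shape)
        if valid.any():
            frac[valid] = np.exp(
                _log_binom(m - mi[valid], tt) - _log_binom(m, tt)
            )
        curve[j] = float(np.sum(1.0 - frac))
    return curve


@dataclass(frozen=True)
class ChaoResult:
    estimate: float
    s_obs: int
    degenerate: bool  # True when m < 2 and the estimate falls back to S_obs


def chao_extrapolate(inc: IncidenceMatrix, bias_corrected: bool = True) -> ChaoResult:
    """Incidence-based Chao richness with the (m-1)/m correction.

    Default (bias-corrected) form: S_obs + ((m-1)/m) * Q1(Q1-1) / (2(Q2+1)),
    which needs no special-casing at Q2 = 0.  ``bias_corrected=False`` gives
    the classic Q1^2 / (2 Q2) form (falling back to the corrected form when
    Q2 = 0).  Always >= S_obs.
    """
    s_obs, m, q1, q2 = inc.s_obs, inc.m, inc.q1, inc.q2
    if m < 2:
        return ChaoResult(float(s_obs), s_obs, True)
    corr = (m - 1) / m
    if bias_corrected or q2 == 0:
        extra = corr * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    else:
        extra = corr * q1 * q1 / (2.0 * q2)
    return ChaoResult(float(s_obs + extra), s_obs, False)


def chao1_abundance(counts) -> float:
    """Abundance-based Chao1 (bias-corrected), provided for comparison."""
    c = np.asarray(counts)
    c = c[c > 0]
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def completeness(inc: IncidenceMatrix) -> float:
    """Observed / Chao-extrapolated richness, in (0, 1]."""
    est = chao_extrapolate(inc).estimate
    if est <= 0:
        raise ValueError("Chao estimate must be positive")
    return inc.s_obs / est


class CompletenessModel:
    """Binomial GLM of completeness on sampling effort and latitude.

    Fits ``completeness ~ n_samples * latitude`` with a logit link on
    continuous proportions (each site weight 1) and exposes sequential
    (Type I) likelihood-ratio chi-square statistics per term, matching
    R's ``anova.glm(test="Chisq")``.

    Attributes (set by :meth:`fit`)
    -------------------------------
    params_ : pd.Series of fitted coefficients
    bse_ : pd.Series of coefficient standard errors
    anova_ : pd.DataFrame with columns term, chisq, df, p
    result_ : the underlying statsmodels results object
    """

    formula = "completeness ~ n_samples * latitude"
    min_samples = 5

    def __init__(self, min_samples: int = 5) -> None:
        self.min_samples = min_samples

    def fit(self, records: pd.DataFrame) -> "CompletenessModel":
        df = records.copy()
        needed = {"completeness", "n_samples", "latitude"}
        if not needed <= set(df.columns):
            raise ValueError(f"records must have columns {sorted(needed)}")
        df = df[df["n_samples"] >= self.min_samples]
        if len(df) < 10:
            raise ValueError("too few eligible sites (need >= 10 with enough samples)")
        if ((df["completeness"] <= 0) | (df["completeness"] > 1)).any():
            raise ValueError("completeness must lie in (0, 1]")
        nested = [
            "completeness ~ 1",
            "completeness ~ n_samples",
            "completeness ~ n_samples + latitude",
            "completeness ~ n_samples * latitude",
        ]
        terms = ["n_samples", "latitude", "n_samples:latitude"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DomainWarning)
            try:
                fits = [
                    smf.glm(f, data=df, family=Binomial()).fit() for f in nested
                ]
            except PerfectSeparationError as err:
                raise RuntimeError(f"completeness GLM did not converge: {err}") from err
        for f in fits:
            if not getattr(f, "converged", True):
                raise RuntimeError("completeness GLM did not converge")
        rows = []
        for i, term in enumerate(terms):
            dev_drop = fits[i].deviance - fits[i + 1].deviance
            ddf = fits[i + 1].df_model - fits[i].df_model
            rows.append(
                {"term": term, "chisq": dev_drop, "df": ddf,
                 "p": float(chi2.sf(dev_drop, ddf))}
            )
        self.result_ = fits[-1]
        self.params_ = self.result_.params
        self.bse_ = self.result_.bse
        self.anova_ = pd.DataFrame(rows)
        self.n_obs_ = len(df)
        return self

    def predict_completeness(self, n_samples, latitude) -> np.ndarray:
        self._check_fitted()
        exog = pd.DataFrame(
            {"n_samples": np.atleast_1d(n_samples),
             "latitude": np.atleast_1d(latitude)}
        )
        return np.asarray(self.result_.predict(exog))

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted; call fit() first")


def fit_completeness_model(records: pd.DataFrame, min_samples: int = 5) -> CompletenessModel:
    """Convenience wrapper returning a fitted :class:`CompletenessModel`."""
    return CompletenessModel(min_samples=min_samples).fit(records)


def predict_pooled_richness(
    s_obs_pooled,
    n_samples,
    latitude,
    model: CompletenessModel,
    extreme_completeness: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Extrapolated richness for pooled-list sites: S_obs / predicted
    completeness.  Returns ``(richness, extreme_flag)``; the flag marks
    predictions that extrapolate more than 1/``extreme_completeness``-fold.
    """
    s = np.atleast_1d(np.asarray(s_obs_pooled, dtype=float))
    comp = model.predict_completeness(n_samples, latitude)
    rich = s / comp
    flag = comp < extreme_completeness
    if rich.size == 1:
        return float(rich[0]), bool(flag[0])
    return rich, flag


def site_richness_table(
    samples: pd.DataFrame, taxon_col: str = "taxon", min_samples_extrapolate: int = 3
) -> pd.DataFrame:
    """Per-site observed / Chao richness and completeness from sample rows.

    Sites with fewer than ``min_samples_extrapolate`` samples keep their
    observed richness but carry no extrapolation (NaN), mirroring the rule
    that extrapolations from fewer than three samples are unreliable.
    """
    rows = []
    for sid, g in samples.groupby("site_id", sort=True):
        inc = IncidenceMatrix.from_samples(g, taxon_col=taxon_col)
        chao = chao_extrapolate(inc)
        eligible = inc.m >= min_samples_extrapolate and inc.s_obs > 0
        rows.append(
            {
                "site_id": sid,
                "n_samples": inc.m,
                "s_obs": inc.s_obs,
                "s_chao": chao.estimate if eligible else np.nan,
                "completeness": inc.s_obs / chao.estimate if eligible else np.nan,
            }
        )
    return pd.DataFrame(rows)
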