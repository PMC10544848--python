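"""Mixed-model frequency contrasts: the three analysis designs.

Each design crosses Unit Type (error/target/source) with Key-Control
(observed unit vs matched Monte-Carlo control) on the log10 frequency at
one level, with the same row's frequencies at the other levels (and
phoneme underspecification at the phoneme level) as covariates, and a
random intercept per speech-error case. Fixed effects use sum contrasts
and are reported ANOVA-style: F, Satterthwaite denominator df, p, and
partial eta squared = F*df1 / (F*df1 + df2). Post-hoc pairwise contrasts
of estimated marginal means (covariates at their grand means) are
adjusted with the studentized-range (Tukey) correction within each
level's family.

The model is estimated by REML with statsmodels' MixedLM; the
Satterthwaite degrees of freedom are computed here by the delta method:
for a contrast l, df = 2 f(θ)² / (∇f' A ∇f) with f(θ) = l' Covβ(θ) l
evaluated on the profiled REML surface and A the inverse observed
information of the variance components θ = (τ², σ²). Multi-df effects
use the eigen-decomposition "squeeze" (df = 2E/(E−q) with
E = Σ νᵢ/(νᵢ−2)). A "residual" fallback (df = N − p) is available and is
used automatically when the random-intercept variance collapses to the
boundary, where the delta method is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from sklearn.decomposition import PCA

import statsmodels.formula.api as smf

from .measures import (
    DEFAULT_PHONEME_MEASURE,
    DEFAULT_SYLLABLE_MEASURE,
    PHONEME_MEASURES,
    SYLLABLE_MEASURES,
    MeasureKey,
    laplace_log,
)

FREQ_COLUMN = {"word": "wordfreq", "syllable": "syllfreq", "phoneme": "phonfreq"}


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """partial eta squared from an F statistic and its degrees of freedom."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("F must be >= 0 and dfs > 0")
    return F * df1 / (F * df1 + df2)


# ---------------------------------------------------------------------------
# designs


@dataclass(frozen=True)
class DesignSpec:
    name: str
    levels: tuple[str, ...]
    unit_types: tuple[str, ...]
    word_outcomes_only: bool
    covariates: dict[str, tuple[str, ...]]  # level -> covariate columns


DESIGNS: dict[str, DesignSpec] = {
    "overall": DesignSpec(
        name="overall",
        levels=("word", "syllable", "phoneme"),
        unit_types=("error", "target", "source"),
        word_outcomes_only=True,
        covariates={
            "word": ("syllfreq", "phonfreq"),
            "syllable": ("wordfreq", "phonfreq"),
            "phoneme": ("wordfreq", "syllfreq", "underspec"),
        },
    ),
    "partial_A": DesignSpec(
        name="partial_A",
        levels=("word", "syllable", "phoneme"),
        unit_types=("target", "source"),
        word_outcomes_only=False,
        covariates={
            "word": ("syllfreq", "phonfreq"),
            "syllable": ("wordfreq", "phonfreq"),
            "phoneme": ("wordfreq", "syllfreq", "underspec"),
        },
    ),
    "partial_B": DesignSpec(
        name="partial_B",
        levels=("syllable", "phoneme"),
        unit_types=("error", "target", "source"),
        word_outcomes_only=False,
        covariates={
            "syllable": ("phonfreq",),
            "phoneme": ("syllfreq", "underspec"),
        },
    ),
}


def long_format(
    case_table: pd.DataFrame, design: DesignSpec | str, level: str
) -> pd.DataFrame:
    """Model frame: one row per case x unit type x key/control.

    The outcome is the transformed frequency at ``level``; covariates are
    the same condition row's transformed frequencies at the other levels
    (plus underspecification for phoneme models), centered. Rows with a
    missing outcome or covariate are dropped (listwise within the level).
    """
    if isinstance(design, str):
        design = DESIGNS[design]
    if level not in design.levels:
        raise ValueError(f"level {level!r} not analyzed under design {design.name!r}")
    df = case_table[case_table["unit_type"].isin(design.unit_types)].copy()
    if design.word_outcomes_only:
        word_cases = case_table.loc[
            (case_table["unit_type"] == "error") & (case_table["outcome"] == "word"),
            "case",
        ].unique()
        df = df[df["case"].isin(word_cases)]
    covs = list(design.covariates[level])
    cols = ["case", "unit_type", "key_control", FREQ_COLUMN[level]] + covs
    frame = df[cols].rename(columns={FREQ_COLUMN[level]: "y"}).dropna()
    for c in covs:
        frame[c] = frame[c] - frame[c].mean()
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# random-intercept GLS machinery (profiled REML surface)


class _RandomInterceptGLS:
    """Closed-form GLS quantities for y = Xb + (1|group) + e.

    V_g = sig2 I + tau2 J; all group sums are vectorized so that
    Covβ(θ) and the profiled REML log-likelihood are cheap to evaluate
    repeatedly for numeric derivatives.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        X, y, groups = X[order], y[order], groups[order]
        _, starts, counts = np.unique(groups, return_index=True, return_counts=True)
        self.n, self.p = X.shape
        self.ng = counts.astype(float)  # group sizes
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.U = np.add.reduceat(X, starts, axis=0)  # group sums of X rows
        self.s = np.add.reduceat(y, starts)  # group sums of y

    def _core(self, tau2: float, sig2: float):
        c = tau2 / (sig2 + self.ng * tau2)  # per-group shrinkage
        XtVX = (self.XtX - (self.U * c[:, None]).T @ self.U) / sig2
        XtVy = (self.Xty - self.U.T @ (c * self.s)) / sig2
        ytVy = (self.yty - float(c @ (self.s**2))) / sig2
        return XtVX, XtVy, ytVy

    def covbeta(self, tau2: float, sig2: float) -> np.ndarray:
        XtVX, _, _ = self._core(tau2, sig2)
        return np.linalg.pinv(XtVX)

    def beta(self, tau2: float, sig2: float) -> np.ndarray:
        XtVX, XtVy, _ = self._core(tau2, sig2)
        return np.linalg.solve(XtVX, XtVy)

    def reml_loglik(self, tau2: float, sig2: float) -> float:
        if sig2 <= 0 or tau2 < 0:
            return -np.inf
        XtVX, XtVy, ytVy = self._core(tau2, sig2)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - float(beta @ XtVy)
        logdetV = float(np.sum((self.ng - 1) * np.log(sig2) + np.log(sig2 + self.ng * tau2)))
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (logdetV + logdetXtVX + rss)


def _numeric_hessian(f, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = rel * np.maximum(np.abs(x), 1e-8)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _numeric_gradient(f, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = rel * np.maximum(np.abs(x), 1e-8)
    g = np.empty(k)
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * h[i])
    return g


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class MixedModelResult:
    anova: pd.DataFrame
    beta: pd.Series
    cov_beta: np.ndarray
    tau2: float
    sigma2: float
    design_info: object
    frame: pd.DataFrame
    covariates: tuple[str, ...]
    df_method: str
    singular: bool
    converged: bool
    _gls: _RandomInterceptGLS = field(repr=False, default=None)
    _theta_cov: np.ndarray = field(repr=False, default=None)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def residual_df(self) -> float:
        return self.n_obs - len(self.beta)

    def contrast_df(self, l: np.ndarray) -> float:
        """Denominator df for a single contrast l'beta."""
        if self.df_method == "residual" or self.singular:
            return self.residual_df
        theta = np.array([self.tau2, self.sigma2])

        def f(t):
            return float(l @ self._gls.covbeta(max(t[0], 0.0), t[1]) @ l)

        grad = _numeric_gradient(f, theta)
        denom = float(grad @ self._theta_cov @ grad)
        if denom <= 0:
            return self.residual_df
        df = 2 * f(theta) ** 2 / denom
        return float(np.clip(df, 1.0, self.residual_df))


def fit_mixed_model(
    frame: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    df_method: str = "satterthwaite",
) -> MixedModelResult:
    """Fit y ~ UnitType * KeyControl + covariates + (1 | case), REML.

    Returns ANOVA-style F tests with partial eta squared for every fixed
    effect. A boundary (zero) random-intercept variance is reported via
    ``singular`` and falls back to residual denominator df.
    """
    if df_method not in ("satterthwaite", "residual"):
        raise ValueError(f"unknown df method {df_method!r}")
    rhs = "C(unit_type, Sum) * C(key_control, Sum)"
    for cov in covariates:
        rhs += f" + {cov}"
    model = smf.mixedlm(f"y ~ {rhs}", data=frame, groups=frame["case"])
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = model.fit(reml=True)
    tau2 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    design_info = model.data.design_info
    X = np.asarray(model.exog)
    y = np.asarray(model.endog)
    groups = pd.factorize(frame["case"])[0]
    gls = _RandomInterceptGLS(X, y, groups)

    singular = tau2 < 1e-8 * (tau2 + sigma2)
    theta = np.array([tau2, sigma2])
    theta_cov = None
    if df_method == "satterthwaite" and not singular:
        H = _numeric_hessian(lambda t: gls.reml_loglik(max(t[0], 0.0), t[1]), theta)
        try:
            theta_cov = np.linalg.inv(-H)
            if not np.all(np.isfinite(theta_cov)) or theta_cov[0, 0] < 0 or theta_cov[1, 1] < 0:
                singular = True
        except np.linalg.LinAlgError:
            singular = True

    beta = gls.beta(tau2, sigma2)
    cov_beta = gls.covbeta(tau2, sigma2)
    names = design_info.column_names
    result = MixedModelResult(
        anova=None,
        beta=pd.Series(beta, index=names),
        cov_beta=cov_beta,
        tau2=tau2,
        sigma2=sigma2,
        design_info=design_info,
        frame=frame,
        covariates=tuple(covariates),
        df_method=df_method,
        singular=singular,
        converged=bool(res.converged),
        _gls=gls,
        _theta_cov=theta_cov,
    )

    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(names))[sl]
        if len(idx) == 0:  # e.g. a single-level factor
            continue
        L = np.zeros((len(idx), len(names)))
        L[np.arange(len(idx)), idx] = 1.0
        rows.append(_f_test(result, term, L))
    result.anova = pd.DataFrame(rows)
    return result


def _f_test(result: MixedModelResult, term: str, L: np.ndarray) -> dict:
    beta = result.beta.values
    C = result.cov_beta
    q = L.shape[0]
    M = L @ C @ L.T
    Minv = np.linalg.pinv(M)
    F = float(beta @ L.T @ Minv @ L @ beta) / q
    if q == 1:
        df2 = result.contrast_df(L[0])
    else:
        # lmerTest-style multi-df squeeze over the eigencontrasts of L C L'
        vals, vecs = np.linalg.eigh(M)
        keep = vals > 1e-12 * vals.max()
        dfs = []
        for v in vecs.T[keep]:
            dfs.append(result.contrast_df(v @ L))
        dfs = [d for d in dfs if d > 2]
        if len(dfs) < q:
            df2 = result.residual_df
        else:
            E = sum(d / (d - 2) for d in dfs)
            df2 = 2 * E / (E - q) if E > q else result.residual_df
    p = float(stats.f.sf(F, q, df2))
    return {
        "effect": term,
        "df1": q,
        "df2": float(df2),
        "F": F,
        "p": p,
        "partial_eta_sq": partial_eta_sq(F, q, df2),
    }


# ---------------------------------------------------------------------------
# estimated marginal means and Tukey post-hocs


def estimated_marginal_means(result: MixedModelResult) -> pd.DataFrame:
    """Cell means of UnitType x KeyControl at the covariate grand means."""
    frame = result.frame
    units = list(pd.unique(frame["unit_type"]))
    kcs = list(pd.unique(frame["key_control"]))
    grid = pd.DataFrame(
        [
            {"unit_type": u, "key_control": k,
             **{c: frame[c].mean() for c in result.covariates}}
            for u in units
            for k in kcs
        ]
    )
    (G,) = patsy.build_design_matrices([result.design_info], grid)
    G = np.asarray(G)
    est = G @ result.beta.values
    se = np.sqrt(np.einsum("ij,jk,ik->i", G, result.cov_beta, G))
    out = grid[["unit_type", "key_control"]].copy()
    out["emmean"] = est
    out["se"] = se
    out.attrs["G"] = G
    return out


def posthoc_tukey(result: MixedModelResult) -> pd.DataFrame:
    """All pairwise contrasts of the cell means, Tukey-adjusted.

    With k cells the adjusted p is P(Q_{k,df} >= |t| * sqrt(2)); for a
    two-cell family this reduces to the unadjusted t-test p.
    """
    emm = estimated_marginal_means(result)
    G = emm.attrs["G"]
    k = len(emm)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = G[i] - G[j]
            est = float(c @ result.beta.values)
            se = float(np.sqrt(c @ result.cov_beta @ c))
            t = est / se if se > 0 else np.nan
            df = result.contrast_df(c)
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df))
            rows.append(
                {
                    "a": f"{emm.unit_type[i]}:{emm.key_control[i]}",
                    "b": f"{emm.unit_type[j]}:{emm.key_control[j]}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "df": df,
                    "p_tukey": min(max(p_adj, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)


def get_contrast(posthocs: pd.DataFrame, a: str, b: str) -> pd.Series:
    """Fetch the a-vs-b row regardless of stored orientation (sign follows a−b)."""
    hit = posthocs[(posthocs["a"] == a) & (posthocs["b"] == b)]
    if len(hit):
        return hit.iloc[0]
    hit = posthocs[(posthocs["a"] == b) & (posthocs["b"] == a)]
    if not len(hit):
        raise KeyError(f"no contrast {a} vs {b}")
    row = hit.iloc[0].copy()
    row["estimate"], row["t"] = -row["estimate"], -row["t"]
    row["a"], row["b"] = a, b
    return row


# ---------------------------------------------------------------------------
# design driver


@dataclass
class DesignResult:
    design: str
    level: str
    n_cases: int
    model: MixedModelResult
    emmeans: pd.DataFrame
    contrasts: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "level": self.level,
            "n_cases": self.n_cases,
            "singular": self.model.singular,
            "anova": self.model.anova.to_dict(orient="records"),
            "emmeans": self.emmeans.drop(columns=[], errors="ignore").to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
        }


def analyze_design(
    case_table: pd.DataFrame,
    design: str | DesignSpec,
    level: str,
    df_method: str = "satterthwaite",
) -> DesignResult:
    """Long-format, fit, and post-hoc one design x level analysis."""
    spec = DESIGNS[design] if isinstance(design, str) else design
    frame = long_format(case_table, spec, level)
    model = fit_mixed_model(frame, covariates=spec.covariates[level], df_method=df_method)
    emm = estimated_marginal_means(model)
    contrasts = posthoc_tukey(model)
    return DesignResult(
        design=spec.name,
        level=level,
        n_cases=frame["case"].nunique(),
        model=model,
        emmeans=emm.drop(columns=[], errors="ignore"),
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# representative-measure selection


def select_representative_measure(
    case_table: pd.DataFrame,
    level: str,
    pin_default: bool = False,
) -> MeasureKey:
    """PCA over the standardized log measures; the measure with the largest
    absolute loading on the first principal component is selected.
    ``pin_default`` short-circuits to the study defaults (token frequency in
    the absolute 10-syllable word frame; token phoneme frequency in the
    syllable-slot frame)."""
    if level == "syllable":
        measures = SYLLABLE_MEASURES
        default = DEFAULT_SYLLABLE_MEASURE
    elif level == "phoneme":
        measures = PHONEME_MEASURES
        default = DEFAULT_PHONEME_MEASURE
    else:
        raise ValueError(f"no measure battery at level {level!r}")
    if pin_default:
        return default
    tags = [m.tag for m in measures]
    data = case_table[tags].dropna()
    if len(data) <= len(tags):
        raise ValueError("fewer units than measures")
    logged = np.log10(data.to_numpy(dtype=float) + 1.0)
    std = logged.std(axis=0, ddof=1)
    if np.any(std == 0):
        std = np.where(std == 0, 1.0, std)
    Z = (logged - logged.mean(axis=0)) / std
    pca = PCA(n_components=1)
    pca.fit(Z)
    loadings = pca.components_[0]
    return measures[int(np.argmax(np.abs(loadings)))]
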