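"""Per-ROI linear mixed-effects inference with FDR and simple slopes.

Each similarity index is modelled per ROI with a REML linear mixed model:
fixed effects are the full factorial of eCFT condition (treatment-coded,
downward reference) x standardized trait anxiety x standardized arousal,
with a random intercept per participant. Wald t-tests use
Satterthwaite-approximated denominator degrees of freedom (fractional df),
computed from the closed-form random-intercept REML profile likelihood.
P-values are Benjamini-Hochberg adjusted per fixed-effect term across ROIs,
separately for each index kind. Simple slopes of the index on anxiety
within each condition are linear combinations of the fixed effects with
their own Satterthwaite df.

Model fitting is delegated to :class:`statsmodels` ``MixedLM``; the
Satterthwaite machinery is implemented here because statsmodels exposes
only normal-approximation tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "LmemResult",
    "fit_index_lmem",
    "fdr_correct",
    "simple_slopes",
    "run_roi_sweep",
    "satterthwaite_df",
]

def _condition_term(reference: str) -> str:
    return f"C(condition, Treatment('{reference}'))"


@dataclass
class LmemResult:
    """Fixed-effect table and simple slopes for one ROI x index kind."""

    roi_label: int
    index_kind: str
    terms: pd.DataFrame  # term, estimate, se, df, t, p (+ p_fdr after sweep)
    slopes: pd.DataFrame  # condition, slope, se, df, t, p
    converged: bool
    singular: bool
    n_obs: int
    n_subjects: int
    sigma2_subject: float
    sigma2_resid: float
    _context: dict = field(default_factory=dict, repr=False)


# --------------------------------------------------------------------------
# Satterthwaite df from the random-intercept REML profile likelihood


class _RemlWorkspace:
    """Precomputed sufficient statistics for fast REML evaluations."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X = X
        self.y = y
        self.n, self.p = X.shape
        codes, _ = pd.factorize(groups)
        self.group_sizes = np.bincount(codes).astype(float)
        g = len(self.group_sizes)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Gx = np.zeros((g, self.p))
        self.Gy = np.zeros(g)
        np.add.at(self.Gx, codes, X)
        np.add.at(self.Gy, codes, y)

    def _shrink(self, s2b: float, s2e: float) -> np.ndarray:
        return s2b / (s2e + self.group_sizes * s2b)

    def info_matrix(self, s2b: float, s2e: float) -> np.ndarray:
        k = self._shrink(s2b, s2e)
        A = (self.XtX - (self.Gx * k[:, None]).T @ self.Gx) / s2e
        return A  # = X' V^{-1} X

    def contrast_var(self, s2b: float, s2e: float, c: np.ndarray) -> float:
        A = self.info_matrix(s2b, s2e)
        return float(c @ np.linalg.solve(A, c))

    def reml_loglike(self, s2b: float, s2e: float) -> float:
        k = self._shrink(s2b, s2e)
        A = self.info_matrix(s2b, s2e)
        b = (self.Xty - self.Gx.T @ (k * self.Gy)) / s2e
        beta = np.linalg.solve(A, b)
        quad = (
            self.yty
            - 2.0 * beta @ self.Xty
            + beta @ self.XtX @ beta
            - np.sum(k * (self.Gy - self.Gx @ beta) ** 2)
        ) / s2e
        logdet_v = float(
            np.sum((self.group_sizes - 1.0) * np.log(s2e)
                   + np.log(s2e + self.group_sizes * s2b))
        )
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf
        return -0.5 * (logdet_v + logdet_a + quad)


def satterthwaite_df(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    c: np.ndarray,
    sigma2_subject: float,
    sigma2_resid: float,
) -> float:
    """Satterthwaite denominator df for the contrast c'beta.

    df = 2 f^2 / (g' A g) with f = Var(c'beta) as a function of the variance
    components, g its gradient, and A the inverse REML information of the
    variance components (numeric derivatives of the closed-form profile
    likelihood). Falls back to the residual df when the random-intercept
    variance collapses to the boundary.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    c = np.asarray(c, float)
    ws = _RemlWorkspace(X, y, np.asarray(groups))
    n, p = ws.n, ws.p
    fallback = float(n - p)
    if sigma2_subject <= 1e-10 * max(sigma2_resid, 1e-300):
        return fallback

    phi = np.array([sigma2_subject, sigma2_resid])
    h = 1e-4 * phi

    def f(v):
        return ws.contrast_var(v[0], v[1], c)

    def ll(v):
        return ws.reml_loglike(v[0], v[1])

    grad = np.zeros(2)
    hess = np.zeros((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        grad[i] = (f(phi + e) - f(phi - e)) / (2 * h[i])
        hess[i, i] = (ll(phi + e) - 2 * ll(phi) + ll(phi - e)) / h[i] ** 2
    e0 = np.array([h[0], 0.0])
    e1 = np.array([0.0, h[1]])
    hess[0, 1] = hess[1, 0] = (
        ll(phi + e0 + e1) - ll(phi + e0 - e1) - ll(phi - e0 + e1) + ll(phi - e0 - e1)
    ) / (4 * h[0] * h[1])

    try:
        cov_phi = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return fallback
    denom = float(grad @ cov_phi @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return fallback
    df = 2.0 * f(phi) ** 2 / denom
    if not np.isfinite(df) or df <= 0:
        return fallback
    return float(min(df, fallback))


def _polish_reml(
    ws: _RemlWorkspace, s2b0: float, s2e0: float, y: np.ndarray
) -> tuple[float, float, bool]:
    """Maximise the closed-form REML over (log s2b, log s2e); best of two starts."""
    from scipy.optimize import minimize

    var_y = max(float(np.var(y)), 1e-300)
    floor = 1e-12 * var_y

    def nll(theta):
        val = ws.reml_loglike(np.exp(theta[0]), np.exp(theta[1]))
        return -val if np.isfinite(val) else 1e300

    # moment start: between-group variance of group means vs pooled residual
    gm = ws.Gy / ws.group_sizes
    mom_b = max(float(np.var(gm)) - var_y / float(np.mean(ws.group_sizes)), floor)
    starts = [
        np.log([max(s2b0, floor), max(s2e0, floor)]),
        np.log([mom_b, max(var_y, floor)]),
    ]
    best: tuple[float, np.ndarray, bool] | None = None
    for x0 in starts:
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400})
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, bool(res.success))
    _, x, ok = best
    s2b, s2e = float(np.exp(x[0])), float(np.exp(x[1]))
    if s2b < floor * 10:
        s2b = 0.0
    return s2b, s2e, ok


# --------------------------------------------------------------------------
# model fitting


def _prepare(records: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    df = records.copy()
    conditions = set(df["condition"].unique())
    if not conditions <= {"upward", "downward"}:
        raise ValueError(f"unexpected conditions {conditions}")
    if len(conditions) < 2:
        raise ValueError("need both upward and downward trials to fit the model")
    for raw, std in (("anxiety", "anxiety_z"), ("arousal", "arousal_z")):
        v = df[raw].astype(float)
        sd = v.std(ddof=0)
        df[std] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    df["value"] = df[value_col].astype(float)
    return df


def _friendly(term: str, reference: str) -> str:
    other = "upward" if reference == "downward" else "downward"
    cond = _condition_term(reference)
    return (
        term.replace(f"{cond}[T.{other}]", f"condition[{other}]")
        .replace("Intercept", "intercept")
    )


def fit_index_lmem(
    records: pd.DataFrame,
    include_nuisance: bool = False,
    df_method: str = "satterthwaite",
    three_way: bool = True,
    reference: str = "downward",
    roi_label: int | None = None,
    index_kind: str | None = None,
) -> LmemResult:
    """REML mixed model for one ROI's index records.

    ``records`` needs columns value, condition, anxiety, arousal,
    subject_id (plus jitter_s / prev_condition when
    ``include_nuisance=True``). Continuous predictors are z-scored before
    entry. ``three_way=False`` drops the condition x anxiety x arousal term
    while keeping all pairwise interactions.
    """
    df = _prepare(records)
    n_subjects = df["subject_id"].nunique()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    cond_term = _condition_term(reference)
    if three_way:
        fixed = f"{cond_term} * anxiety_z * arousal_z"
    else:
        fixed = f"({cond_term} + anxiety_z + arousal_z) ** 2"
    if include_nuisance:
        fixed += " + C(jitter_s) + C(prev_condition)"
    formula = f"value ~ {fixed}"

    model = MixedLM.from_formula(formula, groups="subject_id", data=df)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=True, method="lbfgs")
        converged = bool(getattr(fit, "converged", True))
        s2b0, s2e0 = float(np.asarray(fit.cov_re)[0, 0]), float(fit.scale)
    except (np.linalg.LinAlgError, ValueError) as exc:
        # the gradient optimizer can hit a singular X'V^-1 X while
        # exploring extreme variance ratios (few subjects); recover with
        # the direct closed-form search below
        logger.info("statsmodels MixedLM fit failed (%s); using REML search", exc)
        converged = False
        s2b0 = s2e0 = float(np.var(np.asarray(df["value"], float)))

    X = np.asarray(model.exog, float)
    y = np.asarray(model.endog, float)
    groups = np.asarray(df["subject_id"])
    fe_names = list(model.exog_names)

    # Polish the variance components on the closed-form random-intercept
    # REML profile likelihood. Gradient-based fits occasionally stall on a
    # boundary with inconsistent fixed effects; a direct search over
    # (log s2b, log s2e) from the statsmodels solution and a moment start
    # is cheap and keeps (s2b, s2e), beta, cov(beta) and the Satterthwaite
    # df mutually consistent.
    ws = _RemlWorkspace(X, y, groups)
    s2b, s2e, reml_converged = _polish_reml(ws, s2b0, s2e0, y)
    converged = converged or reml_converged
    singular = s2b <= 1e-6 * max(s2e, 1e-300)
    if not converged:
        logger.warning("mixed model did not converge (roi=%s)", roi_label)

    A = ws.info_matrix(s2b, s2e)
    cov_beta = np.linalg.inv(A)
    b = (ws.Xty - ws.Gx.T @ (ws._shrink(s2b, s2e) * ws.Gy)) / s2e
    beta = np.linalg.solve(A, b)

    rows = []
    for j, name in enumerate(fe_names):
        c = np.zeros(len(beta))
        c[j] = 1.0
        se = float(np.sqrt(cov_beta[j, j]))
        t = beta[j] / se
        if df_method == "satterthwaite":
            ddf = satterthwaite_df(X, y, groups, c, s2b, s2e)
        elif df_method == "residual":
            ddf = float(len(y) - len(beta))
        else:
            raise ValueError(f"unknown df_method {df_method!r}")
        p = 2.0 * stats.t.sf(abs(t), ddf)
        rows.append({"term": _friendly(name, reference), "estimate": beta[j],
                     "se": se, "df": ddf, "t": t, "p": p})
    terms = pd.DataFrame(rows)

    result = LmemResult(
        roi_label=-1 if roi_label is None else int(roi_label),
        index_kind=index_kind or "",
        terms=terms,
        slopes=pd.DataFrame(),
        converged=converged,
        singular=singular,
        n_obs=len(df),
        n_subjects=n_subjects,
        sigma2_subject=s2b,
        sigma2_resid=s2e,
        _context={
            "design_info": model.data.design_info,
            "beta": beta,
            "cov_beta": cov_beta,
            "X": X,
            "y": y,
            "groups": groups,
            "fe_names": fe_names,
            "df_method": df_method,
            "data": df,
        },
    )
    result.slopes = simple_slopes(result)
    return result


def simple_slopes(result: LmemResult, conditions=("downward", "upward")) -> pd.DataFrame:
    """Anxiety slope within each condition, at mean arousal.

    The slope is the contrast d(prediction)/d(anxiety_z) evaluated at the
    given condition with arousal_z = 0, built from the fitted design info;
    its SE comes from the fixed-effect covariance and its df from the same
    Satterthwaite machinery as the term tests.
    """
    ctx = result._context
    if not ctx:
        raise ValueError("result carries no fitting context")
    di = ctx["design_info"]
    rows = []
    for cond in conditions:
        base = pd.DataFrame(
            {"condition": [cond], "anxiety_z": [0.0], "arousal_z": [0.0],
             "jitter_s": [2], "prev_condition": ["none"]}
        )
        plus = base.assign(anxiety_z=1.0)
        (m0,) = patsy.build_design_matrices([di], base)
        (m1,) = patsy.build_design_matrices([di], plus)
        c = np.asarray(m1, float)[0] - np.asarray(m0, float)[0]
        slope = float(c @ ctx["beta"])
        se = float(np.sqrt(c @ ctx["cov_beta"] @ c))
        if ctx["df_method"] == "satterthwaite":
            ddf = satterthwaite_df(
                ctx["X"], ctx["y"], ctx["groups"], c,
                result.sigma2_subject, result.sigma2_resid,
            )
        else:
            ddf = float(len(ctx["y"]) - len(ctx["beta"]))
        t = slope / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), ddf)
        rows.append({"condition": cond, "slope": slope, "se": se,
                     "df": ddf, "t": t, "p": p})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# FDR and the ROI sweep


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def run_roi_sweep(
    index_table: pd.DataFrame,
    retained_rois,
    q: float = 0.05,
    include_nuisance: bool = False,
    df_method: str = "satterthwaite",
    index_kinds=("recall_cft_shift_adjusted", "cft_cft_similarity"),
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Fit every retained ROI x index kind; FDR within term across ROIs.

    Returns (terms table with p_fdr and fdr_significant, simple-slopes
    table, list of per-ROI failures). Per-ROI failures are recorded and the
    sweep continues.
    """
    retained_rois = sorted(int(r) for r in retained_rois)
    all_terms, all_slopes, failures = [], [], []
    for kind in index_kinds:
        sub = index_table[index_table["index_kind"] == kind]
        for roi in retained_rois:
            grp = sub[sub["roi_label"] == roi]
            if grp.empty:
                failures.append({"roi_label": roi, "index_kind": kind,
                                 "error": "no records"})
                continue
            try:
                res = fit_index_lmem(
                    grp, include_nuisance=include_nuisance,
                    df_method=df_method, roi_label=roi, index_kind=kind,
                )
            except Exception as exc:  # keep sweeping on per-ROI failure
                logger.warning("ROI %s (%s) failed: %s", roi, kind, exc)
                failures.append({"roi_label": roi, "index_kind": kind,
                                 "error": str(exc)})
                continue
            t = res.terms.copy()
            t.insert(0, "roi_label", roi)
            t.insert(1, "index_kind", kind)
            t["converged"] = res.converged
            t["singular"] = res.singular
            all_terms.append(t)
            s = res.slopes.copy()
            s.insert(0, "roi_label", roi)
            s.insert(1, "index_kind", kind)
            all_slopes.append(s)

    terms = pd.concat(all_terms, ignore_index=True) if all_terms else pd.DataFrame()
    slopes = pd.concat(all_slopes, ignore_index=True) if all_slopes else pd.DataFrame()
    if not terms.empty:
        terms["p_fdr"] = np.nan
        terms["fdr_significant"] = False
        for (_, _), idx in terms.groupby(["index_kind", "term"]).groups.items():
            p_adj, reject = fdr_correct(terms.loc[idx, "p"].to_numpy(), q=q)
            terms.loc[idx, "p_fdr"] = p_adj
            terms.loc[idx, "fdr_significant"] = reject
    return terms, slopes, failures
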