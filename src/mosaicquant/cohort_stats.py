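"""Cohort-level statistics: exclusions, transforms, and linear mixed models.

The study design has repeated cores per subject spread over several TMAs,
so the outcome (square root of the positive fraction) is modelled with
crossed random intercepts for subject and TMA plus fixed effects for age,
sex and disease.  The REML fit is computed with a closed-form profiled
likelihood: the subject blocks are inverted analytically (each subject
contributes a rank-one update to the identity) and the low-cardinality TMA
factor is folded in through a Woodbury identity, so one evaluation costs
O(n * n_tma^2) and a full fit runs in milliseconds even for hundreds of
subjects.  This keeps large parameter-recovery simulations cheap; the
estimates agree with generic mixed-model software (see the test suite,
which cross-checks against statsmodels and lme4 on small fixtures).

P-values use the normal approximation on t = estimate / SE by default;
Satterthwaite degrees of freedom are available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, SpecValidationError

_GAMMA_FLOOR = 1e-12
_SINGULAR_GAMMA = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification."""

    name: str = "model"
    fixed_effects: Sequence[str] = ("age", "sex")
    random_intercepts: Sequence[str] = ("subject_id", "tma_id")
    outcome: str = "sqrt_fraction"
    subset: Optional[str] = None  # pandas query string, e.g. "tma_id in [1, 2]"

    def validate(self) -> None:
        if len(self.random_intercepts) == 0:
            raise SpecValidationError("random_intercepts must be non-empty")
        if len(self.random_intercepts) > 2:
            raise SpecValidationError("at most two crossed random intercepts supported")


@dataclass
class ExclusionLog:
    n_input_rows: int
    n_under18_rows: int
    n_under18_subjects: int
    n_missing_or_unevaluable_rows: int
    n_remaining_rows: int

    def consistent(self) -> bool:
        return (
            self.n_input_rows
            == self.n_under18_rows
            + self.n_missing_or_unevaluable_rows
            + self.n_remaining_rows
        )


@dataclass
class MixedModelFit:
    name: str
    estimates: Dict[str, float]
    std_errors: Dict[str, float]
    t_values: Dict[str, float]
    p_values: Dict[str, float]
    variance_components: Dict[str, float]  # variances, incl. "residual"
    n_obs: int
    n_subjects: int
    n_dropped_rows: int
    converged: bool
    singular: list
    method: str = "REML"
    df_method: str = "z"
    satterthwaite_df: Dict[str, float] = field(default_factory=dict)
    fitted_values: Optional[pd.Series] = None
    residuals: Optional[pd.Series] = None
    fixed_part: Optional[pd.Series] = None
    random_effect_parts: Dict[str, pd.Series] = field(default_factory=dict)


def apply_exclusions(cohort: pd.DataFrame):
    """Remove under-18 subjects, then rows missing sex/age or unevaluable.

    Returns ``(filtered, ExclusionLog)``; counts always add back up to the
    input row count.
    """
    df = cohort.copy()
    n_input = len(df)
    under18 = df["age"].notna() & (df["age"] < 18)
    n_under18_subjects = df.loc[under18, "subject_id"].nunique()
    df = df[~under18]
    missing = df["sex"].isna() | df["age"].isna()
    if "unevaluable" in df.columns:
        missing |= df["unevaluable"].fillna(False).astype(bool)
    n_missing = int(missing.sum())
    df = df[~missing]
    log = ExclusionLog(
        n_input_rows=n_input,
        n_under18_rows=int(under18.sum()),
        n_under18_subjects=int(n_under18_subjects),
        n_missing_or_unevaluable_rows=n_missing,
        n_remaining_rows=len(df),
    )
    return df, log


def transform_variables(cohort: pd.DataFrame, percent_col: str = "percent_positive") -> pd.DataFrame:
    """Add sqrt_fraction, log_heart_weight and log_bmi columns.

    ``sqrt_fraction = sqrt(percent / 100)``; logs are natural; missing
    values stay missing.
    """
    df = cohort.copy()
    pct = df[percent_col].astype(float)
    if (pct.dropna() < 0).any():
        raise SpecValidationError(f"{percent_col} contains negative values")
    df["sqrt_fraction"] = np.sqrt(pct / 100.0)
    for src, dst in (("heart_weight", "log_heart_weight"), ("bmi", "log_bmi")):
        if src in df.columns:
            vals = df[src].astype(float)
            if (vals.dropna() <= 0).any():
                raise SpecValidationError(f"{src} must be positive where present")
            df[dst] = np.log(vals)
    return df


def build_design(df: pd.DataFrame, fixed_effects: Sequence[str]):
    """Fixed-effect design matrix with intercept.

    ``sex`` codes female = 0, male = 1; ``disease`` expands to treatment
    dummies with Control as reference; ``hcm`` is a single HCM indicator;
    anything else is taken as a numeric column.
    """
    cols = {"(Intercept)": pd.Series(1.0, index=df.index)}
    for fe in fixed_effects:
        if fe == "sex":
            cols["Sex"] = df["sex"].map({"male": 1.0, "female": 0.0, 1: 1.0, 0: 0.0})
        elif fe == "disease":
            cats = sorted(c for c in df["disease"].dropna().unique() if c != "Control")
            for c in cats:
                cols[str(c)] = (df["disease"] == c).astype(float)
        elif fe == "hcm":
            cols["HCM"] = (df["disease"] == "HCM").astype(float)
        elif fe == "age":
            cols["Age"] = df["age"].astype(float)
        else:
            cols[fe] = df[fe].astype(float)
    X = pd.DataFrame(cols, index=df.index)
    return X


class _RemlWorkspace:
    """Precomputed structures for one (y, X, subject, tma) layout.

    Rows are sorted by the blocked (high-cardinality) factor; the second
    factor, if any, enters through a Woodbury correction.
    """

    def __init__(self, y, X, codes1, codes2):
        order = np.argsort(codes1, kind="stable")
        self.order = order
        self.y = y[order]
        self.X = X[order]
        self.c1 = codes1[order]
        self.n, self.p = self.X.shape
        # block boundaries of factor 1
        self.starts = np.flatnonzero(np.r_[True, np.diff(self.c1) != 0])
        self.sizes = np.diff(np.r_[self.starts, self.n]).astype(float)
        self.block_of_row = np.repeat(np.arange(len(self.starts)), self.sizes.astype(int))
        if codes2 is not None:
            c2 = codes2[order]
            self.c2 = c2
            self.T = int(c2.max()) + 1
            self.U = np.zeros((self.n, self.T))
            self.U[np.arange(self.n), c2] = 1.0
        else:
            self.c2 = None
            self.T = 0
            self.U = None
        self.M = np.column_stack([self.X, self.y])

    def _d_inv(self, A, g1):
        """Apply inv(I + g1 * block-ones) to columns of A."""
        bs = np.add.reduceat(A, self.starts, axis=0)
        shrink = (g1 / (1.0 + g1 * self.sizes))[:, None]
        return A - (shrink * bs)[self.block_of_row]

    def core(self, g1, g2):
        """Everything the criterion and the estimates need at (g1, g2)."""
        WM = self._d_inv(self.M, g1)
        logdet = float(np.sum(np.log1p(g1 * self.sizes)))
        if self.U is not None:
            g2 = max(g2, _GAMMA_FLOOR)
            WU = self._d_inv(self.U, g1)
            S = self.U.T @ WU
            C = S + np.eye(self.T) / g2
            UtWM = WU.T @ self.M
            ViM = WM - WU @ np.linalg.solve(C, UtWM)
            sign, ld = np.linalg.slogdet(np.eye(self.T) + g2 * S)
            logdet += float(ld)
        else:
            ViM = WM
        G = self.M.T @ ViM
        p = self.p
        XtViX = G[:p, :p]
        XtViy = G[:p, p]
        ytViy = G[p, p]
        beta = np.linalg.solve(XtViX, XtViy)
        rVir = float(ytViy - XtViy @ beta)
        return beta, XtViX, rVir, logdet, ViM

    def neg2_reml(self, phi):
        # large finite penalty (not inf) so Nelder-Mead arithmetic stays clean
        penalty = 1e30
        g1 = float(np.exp(np.clip(phi[0], -60.0, 60.0)))
        g2 = float(np.exp(np.clip(phi[1], -60.0, 60.0))) if self.U is not None else 0.0
        try:
            beta, XtViX, rVir, logdet, _ = self.core(g1, g2)
        except np.linalg.LinAlgError:
            return penalty
        if not np.isfinite(rVir) or rVir <= 0:
            return penalty
        sign, ld_x = np.linalg.slogdet(XtViX)
        if sign <= 0 or not np.isfinite(ld_x):
            return penalty
        crit = (self.n - self.p) * np.log(rVir) + logdet + ld_x
        return crit if np.isfinite(crit) else penalty

    def neg2_reml_full(self, theta):
        """REML criterion in raw variances (s1^2, [s2^2], se^2); used for
        the numerical Hessian behind Satterthwaite df."""
        se2 = theta[-1]
        if se2 <= 0 or np.any(np.asarray(theta[:-1]) < 0):
            return np.inf
        g1 = theta[0] / se2
        g2 = (theta[1] / se2) if self.U is not None else 0.0
        beta, XtViX, rVir, logdet, _ = self.core(g1, g2)
        n, p = self.n, self.p
        # V = se2 * V0:  log|V| = n log se2 + log|V0|; X'V^-1X = X'V0^-1X/se2
        sign, ld_x = np.linalg.slogdet(XtViX / se2)
        return (n - p) * np.log(se2) + logdet + ld_x + rVir / se2


def _fit_reml(y, X, codes1, codes2):
    ws = _RemlWorkspace(y, X, codes1, codes2)
    q = 2 if ws.U is not None else 1
    res = optimize.minimize(
        ws.neg2_reml,
        x0=np.full(q, np.log(0.5)),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    phi = np.clip(res.x, -60.0, 60.0)
    g1 = float(np.exp(phi[0]))
    g2 = float(np.exp(phi[1])) if q == 2 else 0.0
    beta, XtViX, rVir, logdet, ViM = ws.core(g1, g2)
    sigma_e2 = rVir / (ws.n - ws.p)
    cov_beta = sigma_e2 * np.linalg.inv(XtViX)
    # BLUPs from V0^-1 r  (last column of ViM is V0^-1 y; recompute for r)
    Vir = ViM[:, -1] - ViM[:, :-1] @ beta
    u1 = g1 * np.add.reduceat(Vir, ws.starts)
    re1_sorted = u1[ws.block_of_row]
    fixed_sorted = ws.X @ beta
    fitted_sorted = fixed_sorted + re1_sorted
    re2 = None
    if ws.U is not None:
        u2 = g2 * (ws.U.T @ Vir)
        re2_sorted = u2[ws.c2]
        fitted_sorted = fitted_sorted + re2_sorted
        re2 = np.empty(ws.n)
        re2[ws.order] = re2_sorted
    fitted = np.empty(ws.n)
    fitted[ws.order] = fitted_sorted
    fixed_part = np.empty(ws.n)
    fixed_part[ws.order] = fixed_sorted
    re1 = np.empty(ws.n)
    re1[ws.order] = re1_sorted
    return {
        "ws": ws,
        "converged": bool(res.success),
        "gamma": (g1, g2),
        "beta": beta,
        "cov_beta": cov_beta,
        "sigma_e2": float(sigma_e2),
        "fitted": fitted,
        "fixed_part": fixed_part,
        "re_parts": (re1, re2),
    }


def fit_mixed_model(
    cohort: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    df_method: str = "z",
) -> MixedModelFit:
    """REML fit of the outcome on fixed effects with crossed random
    intercepts; exclusions and transforms must already be applied."""
    spec.validate()
    if df_method not in ("z", "satterthwaite"):
        raise SpecValidationError("df_method must be 'z' or 'satterthwaite'")
    df = cohort.query(spec.subset) if spec.subset else cohort
    Xdf = build_design(df, spec.fixed_effects)
    used = pd.concat([Xdf, df[spec.outcome]], axis=1)
    keep = used.notna().all(axis=1)
    for g in spec.random_intercepts:
        keep &= df[g].notna()
    n_dropped = int((~keep).sum())
    df = df[keep]
    Xdf = Xdf[keep]
    y = df[spec.outcome].to_numpy(float)
    X = Xdf.to_numpy(float)
    names = list(Xdf.columns)
    if len(df) <= X.shape[1] + 1:
        raise InsufficientDataError("too few rows to fit the model")

    groups = [pd.factorize(df[g])[0] for g in spec.random_intercepts]
    re_names = list(spec.random_intercepts)
    singular: list = []
    # a single-level grouping factor is indistinguishable from the intercept;
    # its variance is fixed at zero and flagged (degenerate design)
    multi = [(n, g) for n, g in zip(re_names, groups) if g.max() + 1 > 1]
    dropped_re = [n for n, g in zip(re_names, groups) if g.max() + 1 <= 1]
    for n in dropped_re:
        singular.append(f"{n} has a single level; variance fixed at 0")
    if not multi:
        raise SpecValidationError(
            "every random grouping factor has a single level; the random "
            "structure is unidentifiable"
        )
    re_names = [n for n, _ in multi]
    groups = [g for _, g in multi]
    if len(groups) == 2:
        # block the higher-cardinality factor, Woodbury the other
        n_levels = [g.max() + 1 for g in groups]
        if n_levels[1] > n_levels[0]:
            groups = groups[::-1]
            re_names = re_names[::-1]
        codes1, codes2 = groups
    else:
        codes1, codes2 = groups[0], None

    fit = _fit_reml(y, X, codes1, codes2 if codes2 is not None else None)
    g1, g2 = fit["gamma"]
    sigma_e2 = fit["sigma_e2"]
    var_comp = {re_names[0]: g1 * sigma_e2}
    if g1 < _SINGULAR_GAMMA:
        singular.append("%s variance at boundary" % re_names[0])
    if codes2 is not None:
        var_comp[re_names[1]] = g2 * sigma_e2
        if g2 < _SINGULAR_GAMMA:
            singular.append("%s variance at boundary" % re_names[1])
    for n in dropped_re:
        var_comp[n] = 0.0
    var_comp["residual"] = sigma_e2

    beta = fit["beta"]
    se = np.sqrt(np.diag(fit["cov_beta"]))
    t = beta / se
    sat_df: Dict[str, float] = {}
    if df_method == "z":
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        dfs = _satterthwaite_dfs(fit, var_comp, re_names)
        p = 2.0 * stats.t.sf(np.abs(t), df=dfs)
        sat_df = dict(zip(names, map(float, dfs)))

    fitted = pd.Series(fit["fitted"], index=df.index)
    residuals = pd.Series(y - fit["fitted"], index=df.index)
    re1_part, re2_part = fit["re_parts"]
    re_parts = {re_names[0]: pd.Series(re1_part, index=df.index)}
    if re2_part is not None:
        re_parts[re_names[1]] = pd.Series(re2_part, index=df.index)
    subj_col = "subject_id" if "subject_id" in df.columns else re_names[0]
    return MixedModelFit(
        name=spec.name,
        estimates=dict(zip(names, map(float, beta))),
        std_errors=dict(zip(names, map(float, se))),
        t_values=dict(zip(names, map(float, t))),
        p_values=dict(zip(names, map(float, p))),
        variance_components=var_comp,
        n_obs=len(df),
        n_subjects=int(df[subj_col].nunique()),
        n_dropped_rows=n_dropped,
        converged=fit["converged"],
        singular=singular,
        df_method=df_method,
        satterthwaite_df=sat_df,
        fitted_values=fitted,
        residuals=residuals,
        fixed_part=pd.Series(fit["fixed_part"], index=df.index),
        random_effect_parts=re_parts,
    )


def _satterthwaite_dfs(fit, var_comp, re_names):
    """Satterthwaite df per coefficient from the numerical REML Hessian."""
    ws = fit["ws"]
    theta0 = np.array(
        [var_comp[n] for n in re_names] + [var_comp["residual"]]
    )
    h = np.maximum(1e-4 * np.abs(theta0), 1e-10)
    k = len(theta0)

    def crit(th):
        return ws.neg2_reml_full(th)

    H = np.zeros((k, k))
    f0 = crit(theta0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                crit(theta0 + ei + ej) - crit(theta0 + ei - ej)
                - crit(theta0 - ei + ej) + crit(theta0 - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        var_theta = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(ws.p, ws.n - ws.p)

    se2 = theta0[-1]

    def cov_diag(th):
        g1 = th[0] / th[-1]
        g2 = (th[1] / th[-1]) if ws.U is not None else 0.0
        _, XtViX, _, _, _ = ws.core(g1, g2)
        return th[-1] * np.diag(np.linalg.inv(XtViX))

    c0 = cov_diag(theta0)
    grads = np.zeros((ws.p, k))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        grads[:, i] = (cov_diag(theta0 + ei) - cov_diag(theta0 - ei)) / (2 * h[i])
    dfs = np.empty(ws.p)
    for j in range(ws.p):
        denom = grads[j] @ var_theta @ grads[j]
        dfs[j] = 2.0 * c0[j] ** 2 / denom if denom > 0 else ws.n - ws.p
    return np.clip(dfs, 1.0, None)


def compute_residuals(
    cohort: pd.DataFrame,
    adjust_for: Sequence[str] = ("age", "sex"),
    random_intercepts: Sequence[str] = ("subject_id", "tma_id"),
    outcome: str = "sqrt_fraction",
    subtract_random: Optional[Sequence[str]] = None,
):
    """Outcome residuals after removing covariate and random-intercept
    effects — the adjusted values used for disease-group comparisons.

    ``subtract_random`` lists the random factors whose predicted intercepts
    are subtracted along with the fixed effects; by default all of them are
    (the fully conditional residual).  Subject-level contrasts such as
    disease-group comparisons should pass ``("tma_id",)`` instead: the
    subject intercepts then still guard the fit against pseudo-replication
    but subject-level biology is left in the residual rather than being
    absorbed into it.

    Returns ``(residuals, fit)``; residuals are indexed like the input
    (rows dropped by the fit are absent).
    """
    spec = ModelSpec(
        name="adjustment",
        fixed_effects=tuple(adjust_for),
        random_intercepts=tuple(random_intercepts),
        outcome=outcome,
    )
    fit = fit_mixed_model(cohort, spec)
    if subtract_random is None:
        return fit.residuals, fit
    unknown = set(subtract_random) - set(fit.random_effect_parts)
    if unknown:
        raise SpecValidationError(f"unknown random factors: {sorted(unknown)}")
    adjusted = cohort.loc[fit.fixed_part.index, outcome] - fit.fixed_part
    for name in subtract_random:
        adjusted = adjusted - fit.random_effect_parts[name]
    return adjusted, fit


def default_model_suite() -> list:
    """The four standing analyses of the study design."""
    return [
        ModelSpec(name="all_tmas_age_sex", fixed_effects=("age", "sex")),
        ModelSpec(
            name="tma12_disease",
            fixed_effects=("age", "sex", "disease"),
            subset="tma_id in [1, 2]",
        ),
        ModelSpec(
            name="heart_weight",
            fixed_effects=("age", "sex", "log_heart_weight"),
        ),
        ModelSpec(name="hcm_combined", fixed_effects=("age", "sex", "hcm")),
    ]


def run_model_suite(cohort: pd.DataFrame, specs: Optional[Sequence[ModelSpec]] = None):
    """Fit every model of the suite; failures are isolated per model.

    Returns ``(fits, failures)`` where ``fits`` maps model name to
    :class:`MixedModelFit` and ``failures`` maps name to the error message.
    """
    fits: Dict[str, MixedModelFit] = {}
    failures: Dict[str, str] = {}
    for spec in specs if specs is not None else default_model_suite():
        try:
            fits[spec.name] = fit_mixed_model(cohort, spec)
        except Exception as exc:  # noqa: BLE001 - isolate per-model failures
            failures[spec.name] = f"{type(exc).__name__}: {exc}"
    return fits, failures


def tidy_fits(fits: Dict[str, MixedModelFit]) -> pd.DataFrame:
    """Long coefficient table (model, term, estimate, SE, t, p)."""
    rows = []
    for name, fit in fits.items():
        for term in fit.estimates:
            rows.append(
                {
                    "model": name,
                    "term": term,
                    "estimate": fit.estimates[term],
                    "std_error": fit.std_errors[term],
                    "t_value": fit.t_values[term],
                    "p_value": fit.p_values[term],
                }
            )
        for comp, var in fit.variance_components.items():
            rows.append(
                {
                    "model": name,
                    "term": f"var({comp})",
                    "estimate": var,
                    "std_error": np.nan,
                    "t_value": np.nan,
                    "p_value": np.nan,
                }
            )
    return pd.DataFrame(rows)


def plot_residuals_by_disease(cohort, residuals, out_path):
    """Box plot of adjusted residuals per disease group (file output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cohort.loc[residuals.index].assign(residual=residuals)
    groups = sorted(df["disease"].dropna().unique())
    data = [df.loc[df["disease"] == g, "residual"].to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(groups), 4.0))
    ax.boxplot(data, tick_labels=groups)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("adjusted sqrt-fraction residual")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
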