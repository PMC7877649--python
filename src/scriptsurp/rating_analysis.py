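"""Ordinal mixed-model analysis of Likert acceptability ratings.

Implements the experiment's statistical pipeline: subject exclusion by
performance on ungrammatical controls, sum coding and familiarity
z-scoring, cumulative link mixed models (CLMMs) with crossed by-subject
and by-item random effects, likelihood-ratio tests, and
marginality-respecting backward selection of fixed effects.

The CLMM is a proportional-odds model on a latent logistic scale:

    P(Y <= k | u) = logistic(theta_k - x'beta - z'u),   u ~ N(0, D)

with D diagonal (independent random intercepts and slopes, one variance
per term).  The marginal likelihood is approximated by a Laplace
approximation around the joint mode of the random effects, found by a
damped Newton method (the cumulative-logit log-likelihood is concave in
the linear predictor, so the inner problem is convex).  No installed
package fits this model class, so the estimator is implemented here;
the no-random-effects reduction is cross-checked against
``statsmodels`` ``OrderedModel`` in the test suite.

Estimation is deterministic: thresholds start at the marginal
category-frequency logits, coefficients at zero, random-effect SDs at
0.5, and the outer optimizer (L-BFGS-B on thresholds-as-increments,
coefficients, and log-SDs) uses fixed settings throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import chi2

from scriptsurp.synthetic_data import CODING

__all__ = [
    "ClmmSpec",
    "ClmmFit",
    "DesignData",
    "LRTestResult",
    "exclude_subjects",
    "prepare_design",
    "fit_clmm",
    "lr_test",
    "backward_select",
    "final_model_spec",
    "full_model_spec",
    "load_ratings",
    "feasibility_report",
]

N_CATEGORIES = 7

_REQUIRED = ("subject", "item", "rating")


# ---------------------------------------------------------------------------
# Loading and screening
# ---------------------------------------------------------------------------

def load_ratings(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load a trial-level rating CSV, renaming columns via ``column_map``.

    ``column_map`` maps source column names to the canonical schema
    (subject, item, scenario, rating, sententiality, predictability,
    script_type, position, familiarity_raw, is_control, control_kind),
    accommodating deposited tables whose headers differ.  Missing
    optional columns are tolerated; :func:`feasibility_report` says
    which analyses the loaded table supports.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"rating table lacks required column(s) {missing}")
    df["rating"] = df["rating"].astype(int)
    bad = df[(df["rating"] < 1) | (df["rating"] > N_CATEGORIES)]
    if len(bad):
        raise ValueError(f"{len(bad)} rating(s) outside 1..{N_CATEGORIES}")
    if "is_control" not in df.columns:
        df["is_control"] = False
    exp = df[~df["is_control"].astype(bool)]
    if exp.duplicated(subset=["subject", "item"]).any():
        raise ValueError("duplicate (subject, item) pairs among experimental rows")
    return df


def feasibility_report(df: pd.DataFrame) -> dict[str, bool]:
    """Which pipeline steps the loaded table supports."""
    has_controls = bool(
        df.get("is_control", pd.Series(False, index=df.index)).astype(bool).any()
    )
    return {
        "subject_exclusion": has_controls
        and (df.loc[df["is_control"].astype(bool), "control_kind"] == "ungrammatical").any()
        if "control_kind" in df.columns else has_controls,
        "familiarity_predictor": "familiarity_raw" in df.columns
        and df["familiarity_raw"].notna().any(),
        "script_type_predictor": "script_type" in df.columns,
        "position_predictor": "position" in df.columns,
        "core_model": all(c in df.columns for c in ("sententiality", "predictability")),
    }


def exclude_subjects(df: pd.DataFrame, min_flagged: int = 2,
                     natural_cutoff: int = 6) -> tuple[pd.DataFrame, list[str]]:
    """Drop subjects who rated too many ungrammatical controls as natural.

    A subject is excluded when strictly more than ``min_flagged`` of
    their ungrammatical control trials received a rating of
    ``natural_cutoff`` or above.  All rows of an excluded subject are
    removed.
    """
    if "is_control" not in df.columns or not df["is_control"].astype(bool).any():
        raise ValueError("table contains no control rows; exclusion rule not applicable")
    ctrl = df[df["is_control"].astype(bool)]
    if "control_kind" in df.columns:
        ctrl = ctrl[ctrl["control_kind"] == "ungrammatical"]
    if ctrl.empty:
        raise ValueError("no ungrammatical control rows found")
    flagged = (
        ctrl.assign(natural=ctrl["rating"] >= natural_cutoff)
        .groupby("subject")["natural"].sum()
    )
    excluded = sorted(flagged[flagged > min_flagged].index)
    return df[~df["subject"].isin(excluded)].copy(), list(excluded)


# ---------------------------------------------------------------------------
# Model specification and design preparation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClmmSpec:
    """Fixed and random structure of a cumulative-logit mixed model.

    ``fixed`` lists term names; interactions are colon-joined component
    names and are computed as products of the coded columns.  ``random``
    maps a grouping factor ("subject", "item") to the terms getting a
    random coefficient ("1" is the intercept).  Categorical predictors
    are sum-coded −1/+1; familiarity is z-scored.
    """

    fixed: tuple[str, ...]
    random: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(
            self, "random", {g: tuple(t) for g, t in self.random.items()}
        )

    def drop(self, term: str) -> "ClmmSpec":
        if term not in self.fixed:
            raise ValueError(f"term {term!r} not in spec")
        return ClmmSpec(
            fixed=tuple(t for t in self.fixed if t != term), random=dict(self.random)
        )


def final_model_spec() -> ClmmSpec:
    """The published final model: both manipulations, familiarity, position,
    the Sententiality:Predictability and Predictability:ScriptFamiliarity
    interactions, with by-subject and by-item intercepts and slopes for
    the manipulated factors."""
    return ClmmSpec(
        fixed=(
            "sententiality",
            "predictability",
            "script_familiarity",
            "position",
            "sententiality:predictability",
            "predictability:script_familiarity",
        ),
        random={
            "subject": ("1", "sententiality", "predictability"),
            "item": ("1", "sententiality", "predictability"),
        },
    )


def full_model_spec() -> ClmmSpec:
    """The selection starting point: all main effects, all two-way
    interactions among them, and the three-way
    Sententiality:Predictability:ScriptFamiliarity interaction."""
    mains = ("sententiality", "predictability", "script_type",
             "position", "script_familiarity")
    twoway = tuple(
        f"{a}:{b}" for i, a in enumerate(mains) for b in mains[i + 1:]
    )
    return ClmmSpec(
        fixed=mains + twoway + ("sententiality:predictability:script_familiarity",),
        random={
            "subject": ("1", "sententiality", "predictability"),
            "item": ("1", "sententiality", "predictability"),
        },
    )


@dataclass
class DesignData:
    """Model-ready arrays plus the coded column table they came from."""

    frame: pd.DataFrame          # coded columns, one row per experimental trial
    y: np.ndarray                # 0-based ordinal response codes
    n_missing_familiarity: int = 0
    familiarity_zero_variance: bool = False

    def column(self, term: str) -> np.ndarray:
        """Numeric column for a (possibly interaction) term."""
        if term == "1":
            return np.ones(len(self.frame))
        out = np.ones(len(self.frame))
        for part in term.split(":"):
            if part not in self.frame.columns:
                raise KeyError(f"unknown predictor {part!r}")
            out = out * self.frame[part].to_numpy(dtype=float)
        return out

    def X(self, terms: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.column(t) for t in terms]) if terms else np.empty(
            (len(self.frame), 0)
        )


def prepare_design(df: pd.DataFrame, spec: ClmmSpec | None = None) -> DesignData:
    """Sum-code factors, z-score familiarity, and assemble the design table.

    Control rows are dropped.  Rows with missing familiarity are kept:
    their z-scored familiarity is set to 0 (the z-scale mean) and
    flagged in a ``familiarity_missing`` indicator column, keeping the
    missing-data handling auditable.  The z-transform pools all
    available subject × scenario observations.
    """
    exp = df[~df.get("is_control", pd.Series(False, index=df.index)).astype(bool)].copy()
    if exp.empty:
        raise ValueError("no experimental rows after removing controls")
    out = pd.DataFrame(index=exp.index)
    out["subject"] = exp["subject"].astype(str)
    out["item"] = exp["item"].astype(str)
    for factor, codes in CODING.items():
        if factor not in exp.columns:
            continue
        levels = set(exp[factor].dropna().unique())
        unknown = levels - set(codes)
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} for {factor!r}")
        if len(levels) < 2:
            raise ValueError(f"predictor {factor!r} has a single level; cannot code")
        out[factor] = exp[factor].map(codes).astype(float)
    if "position" in exp.columns:
        out["position"] = exp["position"].astype(float)

    n_missing = 0
    zero_var = False
    if "familiarity_raw" in exp.columns:
        fam = exp["familiarity_raw"].astype(float)
        observed = fam.dropna()
        n_missing = int(fam.isna().sum())
        if len(observed):
            sd = observed.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                zero_var = True
                z = pd.Series(0.0, index=exp.index)
            else:
                z = (fam - observed.mean()) / sd
            out["script_familiarity"] = z.fillna(0.0)
            out["familiarity_missing"] = fam.isna().astype(float)
    y = exp["rating"].astype(int).to_numpy() - 1
    return DesignData(
        frame=out.reset_index(drop=True),
        y=y,
        n_missing_familiarity=n_missing,
        familiarity_zero_variance=zero_var,
    )


# ---------------------------------------------------------------------------
# Laplace CLMM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClmmFit:
    spec: ClmmSpec
    estimates: dict[str, float]
    std_errors: dict[str, float]
    thresholds: tuple[float, ...]
    random_sd: dict[str, float]        # "group:term" -> SD estimate
    loglik: float
    n_obs: int
    converged: bool
    message: str = ""

    @property
    def n_fixed(self) -> int:
        return len(self.estimates)


_P_FLOOR = 1e-12


def _obs_derivs(theta: np.ndarray, eta: np.ndarray, y: np.ndarray):
    """Per-observation log-probability and derivative building blocks.

    With a = θ_upper − η and b = θ_lower − η (±inf at the scale ends),
    returns log p plus the first derivatives of log p with respect to a,
    b and η, and the second-derivative terms (paa, pbb, pab) needed to
    assemble the joint Hessian.  w = −d²logp/dη² ≥ 0 (the ordinal
    logistic log-likelihood is concave in the linear predictor).
    """
    full = np.concatenate([[-np.inf], theta, [np.inf]])
    a = full[y + 1] - eta
    b = full[y] - eta
    Fa, Fb = expit(a), expit(b)
    fa = Fa * (1.0 - Fa)
    fb = Fb * (1.0 - Fb)
    p = np.maximum(Fa - Fb, _P_FLOOR)
    ga = fa / p
    gb = -fb / p
    geta = -(ga + gb)
    dfa = fa * (1.0 - 2.0 * Fa)
    dfb = fb * (1.0 - 2.0 * Fb)
    paa = dfa / p - ga * ga
    pbb = -dfb / p - gb * gb
    pab = fa * fb / (p * p)
    w = np.maximum(-(paa + 2.0 * pab + pbb), 1e-10)
    return np.log(p), ga, gb, geta, paa, pbb, pab, w


def _threshold_coupling(y: np.ndarray, ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """n × (K−1) matrix T with T[i, k] = coefficient coupling obs i to θ_k."""
    n = len(y)
    T = np.zeros((n, N_CATEGORIES - 1))
    has_upper = y < N_CATEGORIES - 1
    has_lower = y > 0
    T[np.nonzero(has_upper)[0], y[has_upper]] += ca[has_upper]
    T[np.nonzero(has_lower)[0], y[has_lower] - 1] += cb[has_lower]
    return T


def _joint_newton(theta0, beta0, u0, X, y, Z, prior_prec,
                  tol=1e-8, max_iter=60):
    """Damped Newton maximizer of the joint penalized log-likelihood.

    Optimizes thresholds, fixed coefficients and random coefficients
    together; the objective is convex, so Newton with step halving
    converges reliably.  Steps producing non-increasing thresholds are
    rejected in the line search.  Returns the mode, the objective value
    there, and the full Hessian (θ, β, u blocks).
    """
    K1 = N_CATEGORIES - 1
    p_dim, q = X.shape[1], Z.shape[1]
    theta, beta, u = theta0.copy(), beta0.copy(), u0.copy()

    def value(theta, beta, u):
        if np.any(np.diff(theta) <= 0):
            return np.inf, None
        eta = (X @ beta if p_dim else 0.0) + (Z @ u if q else 0.0)
        eta = np.asarray(eta) + np.zeros(len(y))
        parts = _obs_derivs(theta, eta, y)
        f = -parts[0].sum() + 0.5 * float(np.dot(u * prior_prec, u))
        return f, parts

    f, parts = value(theta, beta, u)
    if not np.isfinite(f):
        raise ValueError("starting thresholds are not strictly increasing")
    H = None
    for _ in range(max_iter):
        _, ga, gb, geta, paa, pbb, pab, w = parts
        # gradient of the NEGATIVE penalized log-likelihood
        g_theta = np.zeros(K1)
        has_u = y < N_CATEGORIES - 1
        has_l = y > 0
        np.add.at(g_theta, y[has_u], -ga[has_u])
        np.add.at(g_theta, y[has_l] - 1, -gb[has_l])
        g_beta = -(X.T @ geta) if p_dim else np.empty(0)
        g_u = (-(Z.T @ geta) + prior_prec * u) if q else np.empty(0)
        grad = np.concatenate([g_theta, g_beta, g_u])

        # Hessian blocks
        ca = paa + pab
        cb = pbb + pab
        T = _threshold_coupling(y, ca, cb)
        Htt = np.zeros((K1, K1))
        iu = np.nonzero(has_u)[0]
        il = np.nonzero(has_l)[0]
        np.add.at(Htt, (y[iu], y[iu]), -paa[iu])
        np.add.at(Htt, (y[il] - 1, y[il] - 1), -pbb[il])
        both = np.nonzero(has_u & has_l)[0]
        np.add.at(Htt, (y[both], y[both] - 1), -pab[both])
        Htt = Htt + Htt.T - np.diag(np.diag(Htt))  # mirror the sub-diagonal band
        dim = K1 + p_dim + q
        H = np.zeros((dim, dim))
        H[:K1, :K1] = Htt
        if p_dim:
            Htb = T.T @ X
            H[:K1, K1:K1 + p_dim] = Htb
            H[K1:K1 + p_dim, :K1] = Htb.T
            H[K1:K1 + p_dim, K1:K1 + p_dim] = (X * w[:, None]).T @ X
        if q:
            Htu = (Z.T @ T).T  # K1 x q
            H[:K1, K1 + p_dim:] = Htu
            H[K1 + p_dim:, :K1] = Htu.T
            if p_dim:
                Hub = Z.T @ (X * w[:, None])  # q x p
                H[K1:K1 + p_dim, K1 + p_dim:] = Hub.T
                H[K1 + p_dim:, K1:K1 + p_dim] = Hub
            Huu = (Z.T @ sp.diags(w) @ Z).toarray()
            Huu[np.diag_indices_from(Huu)] += prior_prec
            H[K1 + p_dim:, K1 + p_dim:] = Huu

        if np.max(np.abs(grad)) < tol:
            break
        try:
            c, low = cho_factor(H, lower=True)
            step = cho_solve((c, low), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        improved = False
        for _ in range(40):
            theta_n = theta - t * step[:K1]
            beta_n = beta - t * step[K1:K1 + p_dim]
            u_n = u - t * step[K1 + p_dim:]
            f_n, parts_n = value(theta_n, beta_n, u_n)
            if f_n <= f - 1e-4 * t * float(grad @ step):
                theta, beta, u, f, parts = theta_n, beta_n, u_n, f_n, parts_n
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return theta, beta, u, f, H


def _build_random(design: DesignData, spec: ClmmSpec):
    """Sparse Z, per-coefficient term index, and term labels."""
    n = len(design.frame)
    cols, rows, vals = [], [], []
    term_of_coef: list[int] = []
    labels: list[str] = []
    offset = 0
    for group, terms in spec.random.items():
        codes, levels = pd.factorize(design.frame[group], sort=True)
        for term in terms:
            z = design.column(term) if term != "1" else np.ones(n)
            rows.extend(range(n))
            cols.extend(offset + codes)
            vals.extend(z)
            term_of_coef.extend([len(labels)] * len(levels))
            labels.append(f"{group}:{term}")
            offset += len(levels)
    q = offset
    Z = sp.csr_matrix((vals, (rows, cols)), shape=(n, q)) if q else sp.csr_matrix((n, 0))
    return Z, np.asarray(term_of_coef, dtype=int), labels


def fit_clmm(design: DesignData, spec: ClmmSpec,
             compute_se: bool = True, maxiter: int = 200) -> ClmmFit:
    """Maximize the Laplace-approximate CLMM likelihood.

    Thresholds, fixed coefficients and random-effect modes are profiled
    out by an exact damped-Newton solve of the (convex) joint penalized
    likelihood; the outer L-BFGS-B optimization runs over the
    random-effect log-SDs only, minimizing the Laplace objective
    (penalized deviance at the mode plus the log-determinant of the
    random-effects information block).  Standard errors come from the
    Schur complement of the joint Hessian over the threshold/coefficient
    block, conditioning on the estimated variance parameters — the same
    convention mixed-model packages report.

    Deterministic given the data: thresholds start at the marginal
    cumulative-frequency logits, coefficients at zero, SDs at 0.5, with
    fixed optimizer settings.  Non-convergence is reported via the
    ``converged`` flag and ``message``, never silently.
    """
    y = design.y
    n = len(y)
    X = design.X(spec.fixed)
    Z, term_of_coef, sd_labels = _build_random(design, spec)
    n_beta = X.shape[1]
    n_sigma = len(sd_labels)
    q = Z.shape[1]
    K1 = N_CATEGORIES - 1

    counts = np.bincount(y, minlength=N_CATEGORIES).astype(float)
    cum = np.clip(np.cumsum(counts)[:-1] / n, 1e-3, 1 - 1e-3)
    theta0 = np.maximum.accumulate(np.log(cum / (1 - cum)))
    theta0 += np.arange(K1) * 1e-3  # break exact ties, keep strictly increasing

    state = {"theta": theta0, "beta": np.zeros(n_beta), "u": np.zeros(q)}

    def solve_mode(log_sigma: np.ndarray):
        if q:
            sigma2 = np.exp(2.0 * log_sigma)[term_of_coef]
            prior_prec = 1.0 / np.maximum(sigma2, 1e-12)
        else:
            prior_prec = np.empty(0)
        theta, beta, u, f, H = _joint_newton(
            state["theta"], state["beta"], state["u"], X, y, Z, prior_prec
        )
        state.update(theta=theta, beta=beta, u=u)
        return theta, beta, u, f, H

    def laplace_nll(log_sigma: np.ndarray) -> float:
        theta, beta, u, f, H = solve_mode(log_sigma)
        if q == 0:
            return f
        sigma2 = np.exp(2.0 * log_sigma)[term_of_coef]
        Huu = H[K1 + n_beta:, K1 + n_beta:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return 1e10
        return f + 0.5 * float(np.sum(np.log(sigma2))) + 0.5 * logdet

    converged = True
    message = ""
    if n_sigma:
        res = optimize.minimize(
            laplace_nll, np.full(n_sigma, math.log(0.5)),
            method="L-BFGS-B", bounds=[(-4.0, 3.0)] * n_sigma,
            options={"maxiter": maxiter, "ftol": 1e-9},
        )
        log_sigma = res.x
        converged = bool(res.success)
        message = str(res.message)
        nll = laplace_nll(log_sigma)  # re-solve the mode at the optimum
    else:
        log_sigma = np.empty(0)
        nll = laplace_nll(log_sigma)
    theta, beta, u, f, H = solve_mode(log_sigma)

    std_errors = {t: float("nan") for t in spec.fixed}
    if compute_se and n_beta:
        top = H[: K1 + n_beta, : K1 + n_beta]
        if q:
            cross = H[: K1 + n_beta, K1 + n_beta:]
            Huu = H[K1 + n_beta:, K1 + n_beta:]
            try:
                c, low = cho_factor(Huu, lower=True)
                top = top - cross @ cho_solve((c, low), cross.T)
            except np.linalg.LinAlgError:
                top = top - cross @ np.linalg.pinv(Huu) @ cross.T
        try:
            cov = np.linalg.inv(top)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(top)
        bvar = np.diag(cov)[K1:]
        for t, v in zip(spec.fixed, bvar):
            std_errors[t] = float(math.sqrt(v)) if v > 0 else float("nan")

    return ClmmFit(
        spec=spec,
        estimates={t: float(b) for t, b in zip(spec.fixed, beta)},
        std_errors=std_errors,
        thresholds=tuple(float(t) for t in theta),
        random_sd={lab: float(np.exp(ls)) for lab, ls in zip(sd_labels, log_sigma)},
        loglik=-float(nll),
        n_obs=n,
        converged=converged,
        message=message,
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio tests and backward selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p_value: float


def lr_test(full: ClmmFit, reduced: ClmmFit) -> LRTestResult:
    """Likelihood-ratio test of nested CLMM fits (same data, same random structure)."""
    if not set(reduced.spec.fixed) <= set(full.spec.fixed):
        raise ValueError("reduced model's fixed terms are not a subset of the full model's")
    if reduced.spec.random != full.spec.random:
        raise ValueError("models must share the random-effects structure")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fitted to different numbers of observations")
    df = full.n_fixed - reduced.n_fixed
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(chi2.sf(stat, df))
    return LRTestResult(statistic=stat, df=df, p_value=p)


def _droppable(spec: ClmmSpec) -> list[str]:
    """Terms removable without violating marginality (no retained higher-order
    interaction contains them)."""
    out = []
    for term in spec.fixed:
        parts = set(term.split(":"))
        contained = any(
            other != term and parts < set(other.split(":"))
            for other in spec.fixed
        )
        if not contained:
            out.append(term)
    return out


@dataclass(frozen=True)
class SelectionStep:
    term: str
    statistic: float
    df: int
    p_value: float
    dropped: bool


def backward_select(design: DesignData, full_spec: ClmmSpec,
                    alpha: float = 0.05,
                    compute_se: bool = False) -> tuple[ClmmSpec, ClmmFit, list[SelectionStep]]:
    """Iterative least-significant-first removal of droppable fixed terms.

    At each round every droppable term (marginality respected) is
    tested by a likelihood-ratio test against the current model; the
    term with the largest p-value is removed if p >= alpha.  The random
    structure is held fixed.  Returns the final spec, its fit, and the
    full decision trail.
    """
    current = full_spec
    fit = fit_clmm(design, current, compute_se=False)
    trail: list[SelectionStep] = []
    while True:
        candidates = _droppable(current)
        if not candidates:
            break
        results = []
        for term in candidates:
            reduced_fit = fit_clmm(design, current.drop(term), compute_se=False)
            test = lr_test(fit, reduced_fit)
            results.append((term, reduced_fit, test))
        term, reduced_fit, test = max(results, key=lambda r: r[2].p_value)
        if test.p_value >= alpha:
            trail.append(SelectionStep(term, test.statistic, test.df, test.p_value, True))
            current, fit = current.drop(term), reduced_fit
        else:
            for t, _, tst in results:
                trail.append(SelectionStep(t, tst.statistic, tst.df, tst.p_value, False))
            break
    if compute_se:
        fit = fit_clmm(design, current, compute_se=True)
    return current, fit, trail
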