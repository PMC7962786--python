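"""Statistical battery: mixed-model likelihood-ratio tests with crossed
random intercepts, repeated-measures correlation, ordinal event profiles and
behavioral summary tables."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "LrtResult",
    "RmcorrResult",
    "reverse_rating",
    "chance_level",
    "chance_level_display",
    "fit_lmm",
    "lrt_effect",
    "rmcorr",
    "ordinal_profile",
    "summarize_behavior",
]


LOG_RESPONSES = {"log_fixation_duration"}


@dataclass(frozen=True)
class ModelSpec:
    """A linear mixed model: response ~ fixed effects + crossed random intercepts.

    The four primary models enter ``task`` and ``expertise`` without an
    interaction term; fixation durations are log-transformed before fitting
    (and only there).
    """

    response: str
    fixed_effects: tuple[str, ...] = ("task", "expertise")
    random_intercepts: tuple[str, ...] = ("subject", "image")

    def __post_init__(self) -> None:
        if not self.random_intercepts:
            raise ValueError("at least one random intercept is required")


@dataclass
class LrtResult:
    chi2: float
    df: int
    p: float
    full_loglik: float
    reduced_loglik: float


@dataclass
class RmcorrResult:
    r: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Behavioral primitives
# ---------------------------------------------------------------------------


def reverse_rating(raw: int) -> int:
    """Reverse a 1-6 rating so larger means more confident/familiar (7 - raw)."""
    if raw not in range(1, 7):
        raise ValueError(f"rating must be an integer in 1..6, got {raw!r}")
    return 7 - raw


def chance_level(n_alternatives: int) -> float:
    """Guessing accuracy with ``n_alternatives`` equally likely answers."""
    if n_alternatives < 2:
        raise ValueError("need at least 2 answer alternatives")
    return 1.0 / n_alternatives


def chance_level_display(n_alternatives: int) -> float:
    """Chance level truncated (not rounded) to two decimals: 1/6 -> 0.16."""
    return math.floor(chance_level(n_alternatives) * 100) / 100


# ---------------------------------------------------------------------------
# Linear mixed models with crossed random intercepts
# ---------------------------------------------------------------------------


class ConvergenceError(RuntimeError):
    """Raised when an LMM fit fails or is numerically singular."""


def _design(data: pd.DataFrame, fixed_effects: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effect design matrix with intercept."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for eff in fixed_effects:
        levels = sorted(pd.unique(data[eff]))
        if len(levels) < 2:
            raise ValueError(f"fixed effect {eff!r} needs >= 2 levels")
        for lev in levels[1:]:
            cols.append((data[eff] == lev).to_numpy(dtype=float))
            names.append(f"{eff}[{lev}]")
    return np.column_stack(cols), names


def _group_indices(data: pd.DataFrame, col: str) -> np.ndarray:
    return pd.factorize(data[col])[0]


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed_effects: tuple[str, ...],
    random_intercepts: tuple[str, ...] = ("subject", "image"),
) -> dict:
    """Maximum-likelihood fit of a Gaussian LMM with crossed random intercepts.

    The marginal covariance is ``sigma^2 (I + sum_g r_g Z_g Z_g')`` with one
    indicator matrix per random factor and variance ratios ``r_g``. The
    residual variance is profiled out analytically and the profile
    log-likelihood over the (log) ratios is maximized; all linear algebra
    runs through the Woodbury identity, so the cost is cubic in the number
    of random-effect levels, not in the number of observations. REML is
    deliberately not offered: fixed-effect LRTs require ML.
    """
    from scipy.optimize import minimize

    y = data[response].to_numpy(dtype=float)
    X, names = _design(data, fixed_effects)
    n = len(y)

    # sparse one-hot random-effect design, one column block per factor
    blocks = []
    for g in random_intercepts:
        idx = _group_indices(data, g)
        q_g = idx.max() + 1
        Z_g = np.zeros((n, q_g))
        Z_g[np.arange(n), idx] = 1.0
        blocks.append(Z_g)
    Z = np.hstack(blocks)
    block_sizes = [b.shape[1] for b in blocks]
    q = Z.shape[1]

    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    eye_q = np.eye(q)

    def _solve_at(log_ratios: np.ndarray):
        d = np.repeat(np.exp(log_ratios), block_sizes)  # per-column ratio
        C = eye_q + ZtZ * d[None, :]  # I_q + Z'Z D
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            raise np.linalg.LinAlgError("indefinite working matrix")
        W = d[:, None] * np.linalg.inv(C)  # D (I + Z'Z D)^{-1}
        XtVX = XtX - ZtX.T @ W @ ZtX
        XtVX = (XtVX + XtVX.T) / 2.0
        XtVy = Xty - ZtX.T @ (W @ Zty)
        yVy = yty - float(Zty @ W @ Zty)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - float(XtVy @ beta)
        return beta, rss, logdet

    def neg_profile_ll(log_ratios: np.ndarray) -> float:
        if np.any(np.abs(log_ratios) > 30):
            return 1e12
        try:
            _, rss, logdet = _solve_at(log_ratios)
        except np.linalg.LinAlgError:
            return 1e12
        if rss <= 0:
            return 1e12
        return 0.5 * (n * math.log(2 * math.pi * rss / n) + n + logdet)

    x0 = np.zeros(len(block_sizes))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            neg_profile_ll,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise ConvergenceError("LMM profile likelihood failed to converge (singular covariance)")

    log_ratios = res.x
    beta, rss, _ = _solve_at(log_ratios)
    sigma2 = rss / n
    return {
        "loglik": -float(res.fun),
        "beta": dict(zip(names, beta)),
        "sigma2": sigma2,
        "tau2": {g: sigma2 * math.exp(lr) for g, lr in zip(random_intercepts, log_ratios)},
        "n_params": X.shape[1] + len(block_sizes) + 1,
        "n_obs": n,
    }


def lrt_effect(
    data: pd.DataFrame,
    spec: ModelSpec,
    effect: str,
) -> LrtResult:
    """Likelihood-ratio test of one fixed effect.

    Fits the full model and the model with ``effect`` removed (both by ML,
    with the same random intercepts), returning ``2 * delta-loglik`` against
    a chi-square reference with df equal to the number of removed
    parameters.
    """
    if effect not in spec.fixed_effects:
        raise ValueError(f"effect {effect!r} is not in the model's fixed effects")
    n_levels = data[effect].nunique()
    if n_levels < 2:
        raise ValueError(f"effect {effect!r} needs >= 2 observed levels")
    reduced_effects = tuple(e for e in spec.fixed_effects if e != effect)

    full = fit_lmm(data, spec.response, spec.fixed_effects, spec.random_intercepts)
    reduced = fit_lmm(data, spec.response, reduced_effects, spec.random_intercepts)
    chi2 = max(2.0 * (full["loglik"] - reduced["loglik"]), 0.0)
    df = n_levels - 1
    p = float(sps.chi2.sf(chi2, df))
    return LrtResult(chi2=chi2, df=df, p=p, full_loglik=full["loglik"], reduced_loglik=reduced["loglik"])


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------


def rmcorr(table: pd.DataFrame, subject: str = "subject", x: str = "x", y: str = "y") -> RmcorrResult:
    """Common within-subject correlation (ANCOVA decomposition).

    Between-subject means are removed from both variables; the correlation
    of the residuals carries the sign of the common slope, with
    ``df = n_observations - n_subjects - 1``.
    """
    df_tab = table[[subject, x, y]].dropna()
    groups = df_tab.groupby(subject)
    if groups.ngroups < 2:
        raise ValueError("rmcorr needs >= 2 subjects")
    if (groups.size() < 2).any():
        raise ValueError("every subject needs >= 2 observations")
    xc = df_tab[x] - groups[x].transform("mean")
    yc = df_tab[y] - groups[y].transform("mean")
    sxx = float((xc**2).sum())
    syy = float((yc**2).sum())
    if sxx == 0:
        raise ValueError("x has no within-subject variance")
    if syy == 0:
        raise ValueError("y has no within-subject variance")
    sxy = float((xc * yc).sum())
    r = sxy / math.sqrt(sxx * syy)
    dof = len(df_tab) - groups.ngroups - 1
    if dof < 1:
        raise ValueError("not enough observations for rmcorr degrees of freedom")
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(dof / (1.0 - r**2))
        p = 2.0 * float(sps.t.sf(abs(t), dof))
    return RmcorrResult(r=r, df=dof, p=p)


# ---------------------------------------------------------------------------
# Ordinal profiles and summaries
# ---------------------------------------------------------------------------


@dataclass
class OrdinalProfile:
    kind: str
    ordinals: list[int]
    means: list[float]
    ci_low: list[float]
    ci_high: list[float]
    counts: list[int]
    empty_ordinals: list[int] = field(default_factory=list)
    first_event_mean: float = float("nan")
    first_event_sd: float = float("nan")
    first_event_n: int = 0


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    m = float(np.mean(values))
    if len(values) < 2:
        return (float("nan"), float("nan"))
    sem = float(np.std(values, ddof=1)) / math.sqrt(len(values))
    half = float(sps.t.ppf(0.5 + level / 2, len(values) - 1)) * sem
    return (m - half, m + half)


def ordinal_profile(
    events: pd.DataFrame,
    kind: str,
    ordinal_range: tuple[int, int] = (2, 13),
) -> OrdinalProfile:
    """Mean +- 95% CI of an event property by ordinal position in the trial.

    ``events`` needs columns ``ordinal`` and ``value``. First events carry a
    strong central bias and are excluded from the profile but summarized
    separately. Ordinals outside ``ordinal_range`` are excluded; empty bins
    are flagged, never imputed.
    """
    lo, hi = ordinal_range
    first = events.loc[events["ordinal"] == 1, "value"].to_numpy(dtype=float)
    in_range = events[(events["ordinal"] >= lo) & (events["ordinal"] <= hi)]

    ordinals, means, ci_lo, ci_hi, counts, empty = [], [], [], [], [], []
    for k in range(lo, hi + 1):
        vals = in_range.loc[in_range["ordinal"] == k, "value"].to_numpy(dtype=float)
        if len(vals) == 0:
            empty.append(k)
            continue
        ordinals.append(k)
        means.append(float(np.mean(vals)))
        lo_ci, hi_ci = _t_ci(vals)
        ci_lo.append(lo_ci)
        ci_hi.append(hi_ci)
        counts.append(len(vals))
    return OrdinalProfile(
        kind=kind,
        ordinals=ordinals,
        means=means,
        ci_low=ci_lo,
        ci_high=ci_hi,
        counts=counts,
        empty_ordinals=empty,
        first_event_mean=float(np.mean(first)) if len(first) else float("nan"),
        first_event_sd=float(np.std(first, ddof=1)) if len(first) > 1 else float("nan"),
        first_event_n=len(first),
    )


def summarize_behavior(trials: pd.DataFrame, n_alternatives: int = 6, alpha: float = 0.05) -> pd.DataFrame:
    """Group x task summary of accuracy, confidence and familiarity.

    Expects one row per trial with columns ``group, task, correct,
    confidence, familiarity`` (ratings already reversed). Adds marginal
    rows (task ``"all"``) and an ``above_chance`` flag from a one-sided
    binomial test of accuracy against ``1/n_alternatives``.
    """
    required = {"group", "task", "correct", "confidence", "familiarity"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    p0 = chance_level(n_alternatives)

    rows = []
    cells = [(g, t) for g in sorted(trials["group"].unique()) for t in sorted(trials["task"].unique())]
    cells += [(g, "all") for g in sorted(trials["group"].unique())]
    for g, t in cells:
        sel = trials["group"] == g
        if t != "all":
            sel &= trials["task"] == t
        sub = trials[sel]
        n = len(sub)
        k = int(sub["correct"].sum())
        test = sps.binomtest(k, n, p0, alternative="greater") if n else None
        rows.append(
            {
                "group": g,
                "task": t,
                "n_trials": n,
                "accuracy_mean": k / n if n else float("nan"),
                "accuracy_sd": float(sub["correct"].astype(float).std(ddof=1)) if n > 1 else float("nan"),
                "confidence_mean": float(sub["confidence"].mean()) if n else float("nan"),
                "confidence_sd": float(sub["confidence"].std(ddof=1)) if n > 1 else float("nan"),
                "familiarity_mean": float(sub["familiarity"].mean()) if n else float("nan"),
                "familiarity_sd": float(sub["familiarity"].std(ddof=1)) if n > 1 else float("nan"),
                "above_chance": bool(test.pvalue < alpha) if test else False,
            }
        )
    return pd.DataFrame(rows)
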