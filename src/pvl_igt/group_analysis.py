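"""Group-level statistics for IGT/PVL cohorts.

The battery mirrors a standard two-group IGT study: covariate-adjusted
ANCOVA on total net scores, a split-plot (mixed-design) ANCOVA on the five
block net scores with Bonferroni-corrected follow-ups, pooled/Welch t-tests
on demographics and deck counts, Mann-Whitney U comparisons of PVL parameter
estimates, and plain plus case-resampling-bootstrapped Pearson correlations.

The split-plot machinery uses orthonormal within-subject contrasts: with
block-contrast scores Z = Y·Mᵀ regressed on [1, group, covariates], the
block, block x group and block x covariate effects are the summed type-III
sums of squares of the corresponding design terms across the four contrast
variables (the "sphericity assumed" averaged F), with a Greenhouse-Geisser
epsilon reported alongside. Group is effect-coded and covariates centred, so
the block main effect is evaluated at the covariate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

#: covariates entered by default in covariate-adjusted comparisons
DEFAULT_COVARIATES = ("sds", "stai_state", "stai_trait")


@dataclass
class StatResult:
    """One test's report: statistic, df/sample sizes, p, effect size."""

    test: str
    statistic: float
    df: tuple[float, ...] | None = None
    n: tuple[int, ...] | None = None
    p: float = np.nan
    effect_size: float | None = None
    adjustment: str = "none"
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": "/".join(f"{d:g}" for d in self.df) if self.df else "",
            "n": "/".join(str(v) for v in self.n) if self.n else "",
            "p": self.p,
            "effect_size": self.effect_size,
            "adjustment": self.adjustment,
        }


def results_table(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def _design(group: np.ndarray, covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    """[1, effect-coded group, centred covariates]; checks full rank."""
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    g = np.where(group == levels[0], 1.0, -1.0)
    cols = [np.ones(len(g)), g]
    names = ["intercept", "group"]
    if covariates is not None and covariates.shape[1]:
        for name in covariates.columns:
            v = covariates[name].to_numpy(float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"covariate {name!r} has missing values")
            cols.append(v - v.mean())
            names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates?)")
    return X, names


def _term_f(y: np.ndarray, X: np.ndarray, col: int) -> tuple[float, float, float, float, float]:
    """Type-III F for one design column: (F, df1, df2, p, partial eta^2)."""
    n, p = X.shape
    fit_full = sm.OLS(y, X).fit()
    sse_full = float(fit_full.ssr)
    X_red = np.delete(X, col, axis=1)
    sse_red = float(sm.OLS(y, X_red).fit().ssr)
    ss_term = sse_red - sse_full
    df2 = n - p
    scale = max(float(np.sum((y - y.mean()) ** 2)), 1.0)
    if sse_full <= 1e-12 * scale:
        # perfectly fitting model: no residual variance
        return (0.0, 1.0, df2, 1.0, 0.0) if ss_term <= 1e-10 * scale else (np.inf, 1.0, df2, 0.0, 1.0)
    F = (ss_term / 1.0) / (sse_full / df2)
    F = max(F, 0.0)
    p_val = float(stats.f.sf(F, 1, df2))
    eta = ss_term / (ss_term + sse_full) if (ss_term + sse_full) > 0 else 0.0
    return F, 1.0, df2, p_val, eta


def ancova_group(
    outcome,
    group,
    covariates: pd.DataFrame | None = None,
    label: str = "ancova_group",
) -> StatResult:
    """One-way ANCOVA: outcome ~ group + covariates; reports the group F.

    With no covariates this is exactly the one-way ANOVA F.
    """
    y = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    X, names = _design(group, covariates)
    if min((group == lv).sum() for lv in pd.unique(group)) < 2:
        raise ValueError("need at least 2 subjects per group")
    F, df1, df2, p, eta = _term_f(y, X, names.index("group"))
    return StatResult(
        test=label, statistic=F, df=(df1, df2), p=p, effect_size=eta,
        n=tuple(int((group == lv).sum()) for lv in pd.unique(group)),
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the constant."""
    H = np.zeros((k - 1, k))
    for i in range(k - 1):
        H[i, : i + 1] = 1.0
        H[i, i + 1] = -(i + 1)
        H[i] /= np.linalg.norm(H[i])
    return H


def _gg_epsilon(Z: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast-score residual covariance."""
    d = Z.shape[1]
    R = Z - Z.mean(axis=0)
    S = R.T @ R / max(len(Z) - 1, 1)
    tr = np.trace(S)
    denom = d * np.sum(S * S)
    return float(tr**2 / denom) if denom > 0 else 1.0


@dataclass
class MixedAnovaResult:
    group: StatResult
    block: StatResult
    interaction: StatResult
    gg_epsilon: float


def mixed_block_ancova(
    block_scores,
    group,
    covariates: pd.DataFrame | None = None,
) -> MixedAnovaResult:
    """Split-plot ANCOVA: block (within, 5 levels) x group (between) with
    covariates, sphericity-assumed F tests plus the GG epsilon."""
    Y = np.asarray(block_scores, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 5:
        raise ValueError("block_scores must be subjects x 5 blocks")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing block scores")
    group = np.asarray(group)
    X, names = _design(group, covariates)
    n, p = X.shape
    d = Y.shape[1] - 1

    # between-subjects part: ANCOVA on the subject means
    m = Y.mean(axis=1)
    Fb, _, dfb2, pb, etab = _term_f(m, X, names.index("group"))
    between = StatResult("mixed_group", Fb, df=(1.0, dfb2), p=pb, effect_size=etab)

    # within-subjects part via orthonormal contrast scores
    M = _orthonormal_contrasts(Y.shape[1])
    Z = Y @ M.T  # (n, 4)
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    resid = Z - X @ beta
    sse = float(np.sum(resid**2))
    df_err = d * (n - p)

    z_scale = max(float(np.sum(Z**2)), 1.0)

    def within_term(col: int, test: str) -> StatResult:
        X_red = np.delete(X, col, axis=1)
        beta_r, *_ = np.linalg.lstsq(X_red, Z, rcond=None)
        ss_term = float(np.sum((Z - X_red @ beta_r) ** 2)) - sse
        ss_term = max(ss_term, 0.0)
        if sse <= 1e-12 * z_scale:
            F, p_val = (0.0, 1.0) if ss_term <= 1e-10 * z_scale else (np.inf, 0.0)
        else:
            F = (ss_term / d) / (sse / df_err)
            p_val = float(stats.f.sf(F, d, df_err))
        eta = ss_term / (ss_term + sse) if (ss_term + sse) > 0 else 0.0
        return StatResult(test, F, df=(float(d), float(df_err)), p=p_val, effect_size=eta)

    block = within_term(names.index("intercept"), "mixed_block")
    interaction = within_term(names.index("group"), "mixed_block_x_group")
    return MixedAnovaResult(
        group=between, block=block, interaction=interaction, gg_epsilon=_gg_epsilon(Z)
    )


def per_block_group_contrasts(
    block_scores, group, covariates: pd.DataFrame | None = None
) -> list[StatResult]:
    """Follow-up ANCOVA per block, tagged with the Bonferroni family size."""
    Y = np.asarray(block_scores, dtype=float)
    out = []
    k = Y.shape[1]
    for b in range(k):
        r = ancova_group(Y[:, b], group, covariates, label=f"block{b + 1}_group")
        r.adjustment = f"bonferroni_{k}"
        out.append(r)
    return out


def per_group_block_anova(block_scores, group) -> list[StatResult]:
    """Follow-up repeated-measures ANOVA across blocks within each group."""
    Y = np.asarray(block_scores, dtype=float)
    group = np.asarray(group)
    M = _orthonormal_contrasts(Y.shape[1])
    d = Y.shape[1] - 1
    out = []
    levels = list(pd.unique(group))
    for lv in levels:
        Zg = Y[group == lv] @ M.T
        ng = len(Zg)
        zbar = Zg.mean(axis=0)
        ss_block = ng * float(zbar @ zbar)
        sse = float(np.sum((Zg - zbar) ** 2))
        df_err = d * (ng - 1)
        z_scale = max(float(np.sum(Zg**2)), 1.0)
        if sse <= 1e-12 * z_scale:
            F, p_val = (0.0, 1.0) if ss_block <= 1e-10 * z_scale else (np.inf, 0.0)
        else:
            F = (ss_block / d) / (sse / df_err)
            p_val = float(stats.f.sf(F, d, df_err))
        eta = ss_block / (ss_block + sse) if (ss_block + sse) > 0 else 0.0
        out.append(
            StatResult(
                f"blocks_within_{lv}", F, df=(float(d), float(df_err)), p=p_val,
                effect_size=eta, n=(ng,), adjustment=f"bonferroni_{len(levels)}",
                extra={"gg_epsilon": _gg_epsilon(Zg)},
            )
        )
    return out


def mann_whitney(x, y, label: str = "mann_whitney") -> StatResult:
    """Mann-Whitney U with midranks.

    Reports min(U_x, n1·n2 − U_x) as the statistic (the reporting
    convention for two-sided group comparisons); the exact null distribution
    is used for untied samples with n1·n2 <= 400, the tie-corrected normal
    approximation otherwise. One-sided ps are in ``extra``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u_y = n1 * n2 - u_x
    if np.ptp(np.concatenate([x, y])) == 0:
        # every observation tied: no evidence either way
        return StatResult(
            test=label, statistic=min(u_x, u_y), n=(n1, n2), p=1.0,
            extra={"u_x": u_x, "u_y": u_y, "p_greater_x": 1.0,
                   "p_less_x": 1.0, "method": "degenerate"},
        )
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (not has_ties and n1 * n2 <= 400) else "asymptotic"
    p_two = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    p_greater = float(stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue)
    p_less = float(stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue)
    return StatResult(
        test=label, statistic=min(u_x, u_y), n=(n1, n2), p=p_two,
        extra={"u_x": u_x, "u_y": u_y, "p_greater_x": p_greater,
               "p_less_x": p_less, "method": method},
    )


def pearson_r(x, y, label: str = "pearson_r") -> StatResult:
    """Pearson product-moment r with the two-sided t-transform p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return StatResult(test=label, statistic=float(r), n=(len(x),), p=float(p))


def bootstrap_pearson(
    x, y, n_boot: int = 10_000, seed: int | None = None,
    label: str = "bootstrap_pearson", max_redraw: int = 100,
) -> StatResult:
    """Case-resampling bootstrap of Pearson's r.

    Reports the observed r, the percentile 95% CI over ``n_boot`` resamples
    and a sign-crossing bootstrap p (twice the smaller tail proportion of
    resampled r's beyond 0, capped at 1). Degenerate resamples are redrawn
    a bounded number of times, then dropped with a recorded count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need equal-length samples with n >= 5")
    rng = np.random.default_rng(seed)
    n = len(x)
    obs = float(stats.pearsonr(x, y)[0]) if (np.std(x) > 0 and np.std(y) > 0) else 1.0

    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    yb = y[idx]
    sx = xb.std(axis=1)
    sy = yb.std(axis=1)
    bad = (sx == 0) | (sy == 0)
    dropped = 0
    for _ in range(max_redraw):
        if not bad.any():
            break
        redo = rng.integers(0, n, size=(int(bad.sum()), n))
        xb[bad], yb[bad] = x[redo], y[redo]
        sx[bad], sy[bad] = xb[bad].std(axis=1), yb[bad].std(axis=1)
        bad = (sx == 0) | (sy == 0)
    if bad.any():
        dropped = int(bad.sum())
        xb, yb, sx, sy = xb[~bad], yb[~bad], sx[~bad], sy[~bad]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rb = (xc * yc).sum(axis=1) / denom
    rb = rb[np.isfinite(rb)]
    lo, hi = np.percentile(rb, [2.5, 97.5])
    frac_neg = float(np.mean(rb < 0))
    frac_pos = float(np.mean(rb > 0))
    p_boot = min(1.0, 2.0 * min(frac_neg, frac_pos))
    return StatResult(
        test=label, statistic=obs, n=(n,), p=p_boot,
        extra={"ci_low": float(lo), "ci_high": float(hi),
               "n_boot": len(rb), "dropped": dropped},
    )


def welch_t(x, y, pooled: bool = True, label: str = "t_test") -> StatResult:
    """Two-sample t-test, pooled-variance by default (Welch by flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    df = float(len(x) + len(y) - 2) if pooled else float(res.df)
    return StatResult(
        test=label, statistic=float(res.statistic), df=(df,),
        n=(len(x), len(y)), p=float(res.pvalue),
        extra={"variant": "pooled" if pooled else "welch"},
    )


def run_standard_analysis(
    scores: pd.DataFrame,
    estimates: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """The full study battery on joined score/estimate/subject tables.

    ``scores``: per-subject total_net, block1..block5, count_A..count_D;
    ``estimates``: per-subject a, lam, A, c; ``subjects``: group + covariates.
    Returns a long results table.
    """
    df = subjects.merge(scores.drop(columns=["group"], errors="ignore"), on="subject_id")
    df = df.merge(
        estimates.drop(columns=["group"], errors="ignore"), on="subject_id"
    )
    grp = df["group"].to_numpy()
    levels = list(pd.unique(grp))
    cov = df[list(covariates)]
    results: list[StatResult] = []

    for var in ("age", "bmi", "sds", "stai_state", "stai_trait", "keat26"):
        if var in df.columns:
            results.append(
                welch_t(df.loc[grp == levels[0], var], df.loc[grp == levels[1], var],
                        label=f"t_{var}")
            )
    results.append(ancova_group(df["total_net"], grp, cov, label="ancova_total_net"))
    blocks = df[[f"block{i}" for i in range(1, 6)]].to_numpy(float)
    mixed = mixed_block_ancova(blocks, grp, cov)
    results.extend([mixed.group, mixed.block, mixed.interaction])
    results.extend(per_block_group_contrasts(blocks, grp, cov))
    results.extend(per_group_block_anova(blocks, grp))
    for d in "ABCD":
        results.append(
            welch_t(df.loc[grp == levels[0], f"count_{d}"],
                    df.loc[grp == levels[1], f"count_{d}"], label=f"t_count_{d}")
        )
    for p in ("a", "lam", "A", "c"):
        results.append(
            mann_whitney(df.loc[grp == levels[0], p], df.loc[grp == levels[1], p],
                         label=f"mann_whitney_{p}")
        )
    rng_seeds = np.random.SeedSequence(seed if seed is not None else 0).spawn(64)
    si = 0
    for lv in levels:
        sub = df[grp == lv]
        results.append(
            pearson_r(sub["total_net"], sub["keat26"], label=f"r_totalnet_keat26_{lv}")
        )
        for p in ("a", "lam", "A", "c"):
            results.append(
                bootstrap_pearson(
                    sub["total_net"], sub[p], n_boot=n_boot,
                    seed=int(rng_seeds[si].generate_state(1)[0] % 2**31),
                    label=f"boot_r_totalnet_{p}_{lv}",
                )
            )
            si += 1
    table = results_table(results)
    for extra_col in ("ci_low", "ci_high"):
        table[extra_col] = [r.extra.get(extra_col) for r in results]
    return table
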