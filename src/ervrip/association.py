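"""Fixed-effects association of marker genotypes with quantitative traits.

The model is the additive fixed-effects ANOVA

    Y_ijkl = mu + G_i + B_j + S_k + e_ijkl

with genotype G (+/+, +/-, -/-), breed B, sex S and Normal(0, sigma_e^2)
residuals, fitted by ordinary least squares with reference-cell coding.
Factor tests use partial (drop-one) sums of squares, which for this additive
no-interaction design coincide with SAS Type III. Pairwise level comparisons
use the least significant difference at alpha = 0.05 with a compact letter
display, and the whole analysis is gated by a Shapiro-Wilk normality check
(W >= 0.90 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_FACTORS = ("genotype", "breed", "sex")


class DegenerateDataError(ValueError):
    """Input values carry no usable variation (e.g. all equal)."""


class AliasingError(ValueError):
    """Factors are completely confounded and their effects are inestimable."""


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------


def normality_gate(values: Sequence[float], w_threshold: float = 0.90) -> tuple:
    """Shapiro-Wilk W and whether it clears the analysis threshold."""
    arr = np.asarray(values, dtype=float)
    if not 3 <= arr.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise DegenerateDataError("all values identical; W is undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for near-constant input
        w, _ = stats.shapiro(arr)
    return float(w), bool(w >= w_threshold)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


@dataclass
class AnovaFit:
    trait: str
    coefficients: pd.Series
    ss_per_factor: Mapping[str, float]
    df_per_factor: Mapping[str, int]
    f_per_factor: Mapping[str, float]
    p_per_factor: Mapping[str, float]
    mse: float
    df_error: int
    n_used: int
    factors: tuple
    dropped_factors: tuple
    level_stats: Mapping[str, pd.DataFrame] = field(default_factory=dict)


def _design_matrix(data: pd.DataFrame, factors: Sequence[str]):
    """Intercept + treatment-coded dummies; returns (X, column map)."""
    columns = {"Intercept": np.ones(len(data))}
    col_factor = {"Intercept": None}
    for factor in factors:
        levels = sorted(data[factor].astype(str).unique())
        for level in levels[1:]:
            name = f"{factor}[{level}]"
            columns[name] = (data[factor].astype(str) == level).to_numpy(float)
            col_factor[name] = factor
    X = pd.DataFrame(columns, index=data.index)
    return X, col_factor


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_glm(
    records: pd.DataFrame,
    trait: str,
    factors: Sequence[str] = DEFAULT_FACTORS,
) -> AnovaFit:
    """Fit Y = mu + G + B + S + e by OLS and test factors by partial SS.

    Factors with a single observed level are dropped with a warning;
    completely confounded factors raise :class:`AliasingError` naming them
    rather than being dropped silently.
    """
    data = records.dropna(subset=[trait, *factors]).copy()
    kept, dropped = [], []
    for factor in factors:
        if data[factor].astype(str).nunique() >= 2:
            kept.append(factor)
        else:
            dropped.append(factor)
            warnings.warn(
                f"factor {factor!r} has a single observed level and was dropped",
                stacklevel=2,
            )
    if not kept:
        raise ValueError("no factor has two or more observed levels")

    y = data[trait].to_numpy(float)
    X, col_factor = _design_matrix(data, kept)
    Xv = X.to_numpy()
    rank_full = np.linalg.matrix_rank(Xv)
    if rank_full < X.shape[1]:
        # a factor is confounded when its columns add no rank beyond the rest
        aliased = []
        for factor in kept:
            fac_cols = [c for c, f in col_factor.items() if f == factor]
            others = X.drop(columns=fac_cols).to_numpy()
            if np.linalg.matrix_rank(others) == rank_full:
                aliased.append(factor)
        raise AliasingError(
            "design is rank deficient; confounded factors: "
            + (", ".join(aliased) if aliased else "undetermined")
        )

    if len(data) <= rank_full:
        raise ValueError("more parameters than observations")

    model = sm.OLS(y, Xv)
    fitted = model.fit()
    sse_full = float(fitted.ssr)
    df_error = len(data) - rank_full
    mse = sse_full / df_error

    ss: dict = {}
    dfs: dict = {}
    fstat: dict = {}
    pval: dict = {}
    for factor in kept:
        fac_cols = [c for c, f in col_factor.items() if f == factor]
        reduced = X.drop(columns=fac_cols).to_numpy()
        ss_f = _sse(y, reduced) - sse_full
        df_f = len(fac_cols)
        ss[factor] = max(ss_f, 0.0)
        dfs[factor] = df_f
        if mse > 0:
            fstat[factor] = (ss[factor] / df_f) / mse
            pval[factor] = float(stats.f.sf(fstat[factor], df_f, df_error))
        else:
            fstat[factor] = np.inf if ss[factor] > 0 else 0.0
            pval[factor] = 0.0 if ss[factor] > 0 else 1.0

    level_stats = {
        factor: data.groupby(data[factor].astype(str))[trait]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
        .rename(columns={factor: "level"})
        for factor in kept
    }
    return AnovaFit(
        trait=trait,
        coefficients=pd.Series(fitted.params, index=X.columns),
        ss_per_factor=ss,
        df_per_factor=dfs,
        f_per_factor=fstat,
        p_per_factor=pval,
        mse=mse,
        df_error=df_error,
        n_used=len(data),
        factors=tuple(kept),
        dropped_factors=tuple(dropped),
        level_stats=level_stats,
    )


# ---------------------------------------------------------------------------
# LSD pairwise comparisons and compact letter display
# ---------------------------------------------------------------------------


@dataclass
class LSDResult:
    factor: str
    alpha: float
    means: pd.Series  # level -> mean, descending
    nobs: pd.Series
    pairs: pd.DataFrame  # level_a, level_b, difference, lsd_threshold, significant
    letter_groups: Mapping[str, str]


def lsd_pairwise(fit: AnovaFit, factor: str, alpha: float = 0.05) -> LSDResult:
    """All pairwise level comparisons by the least significant difference.

    A pair differs when |mean_i - mean_j| exceeds
    t(1 - alpha/2, df_error) * sqrt(mse (1/n_i + 1/n_j)); letters are
    assigned so that levels sharing a letter are never flagged different
    (maximal sets of mutually non-significant levels, best mean first).
    """
    if factor not in fit.factors:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    statsdf = fit.level_stats[factor]
    if len(statsdf) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")
    means = statsdf.set_index("level")["mean"].sort_values(ascending=False)
    nobs = statsdf.set_index("level")["n"].reindex(means.index)
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_error)
    rows = []
    graph = nx.Graph()
    graph.add_nodes_from(means.index)
    levels = list(means.index)
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            threshold = tcrit * np.sqrt(fit.mse * (1 / nobs[a] + 1 / nobs[b]))
            diff = means[a] - means[b]
            significant = abs(diff) > threshold
            rows.append(
                {
                    "level_a": a,
                    "level_b": b,
                    "difference": diff,
                    "lsd_threshold": threshold,
                    "significant": significant,
                }
            )
            if not significant:
                graph.add_edge(a, b)
    cliques = list(nx.find_cliques(graph))
    cliques.sort(key=lambda c: -max(means[lvl] for lvl in c))
    letters: dict = {lvl: "" for lvl in levels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for lvl in clique:
            letters[lvl] += letter
    letters = {lvl: "".join(sorted(ls)) for lvl, ls in letters.items()}
    return LSDResult(
        factor=factor,
        alpha=alpha,
        means=means,
        nobs=nobs,
        pairs=pd.DataFrame(rows),
        letter_groups=letters,
    )


def means_table(fit: AnovaFit, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Mean +/- SD with significance letters, one row per level."""
    lsd = lsd_pairwise(fit, factor, alpha=alpha)
    statsdf = fit.level_stats[factor].set_index("level")
    rows = []
    for level in lsd.means.index:
        rows.append(
            {
                "level": level,
                "n": int(statsdf.loc[level, "n"]),
                "mean": statsdf.loc[level, "mean"],
                "sd": statsdf.loc[level, "sd"],
                "letters": lsd.letter_groups[level],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration utility
# ---------------------------------------------------------------------------


def null_rejection_rate(
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_per_breed: int = 72,
) -> float:
    """Genotype F-test rejection rate when all genotype effects are equal.

    Simulates breed/sex-structured populations with zero genotype effect and
    returns the share of replicates with p < alpha; a calibrated test sits
    near alpha.
    """
    from .simulate import PopulationSpec, simulate_population

    rejections = 0
    for rep in range(n_replicates):
        spec = PopulationSpec(
            breeds=(("B1", n_per_breed, 0.5), ("B2", n_per_breed, 0.4)),
            mu=3.0,
            genotype_effects={"+/+": 0.0, "+/-": 0.0, "-/-": 0.0},
            breed_effects={"B1": 0.0, "B2": 0.6},
            sex_effects={"M": 0.2, "F": 0.0},
            residual_sd=0.5,
            seed=seed * 1_000_003 % (2**31) + rep,
        )
        data = simulate_population(spec)
        fit = fit_glm(data, "trait")
        if fit.p_per_factor["genotype"] < alpha:
            rejections += 1
    return rejections / n_replicates
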