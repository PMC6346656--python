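"""Marker-cognition association: transforms, screening, AICc subset selection.

The outcome is the MMSE global cognition score (0-30), log-transformed for
normality and rescaled to z-scores; all markers and covariates are likewise
z-scored. Three layers of analysis:

* **Univariate screening** — each marker enters its own linear model with
  the covariates age, sex and education; the marker term is tested by an
  F-test (equivalently the squared t).
* **Marker intercorrelation** — the Pearson matrix with a two-tailed
  t-based significance mask.
* **Multiple regression with all-subset selection** — every subset of the
  candidate markers up to a size cap is fitted by OLS (covariates always
  included) and ranked by the corrected Akaike information criterion

      AICc = n ln(RSS/n) + 2 k' + 2 k'(k'+1) / (n - k' - 1),

  with k' the parameter count including the intercept. Exhaustive
  enumeration is made tractable by solving every subset's normal equations
  from one precomputed Gram matrix, batched per subset size; the detailed
  fit (standard errors, t, p) of the winning subsets is then produced by
  statsmodels.

Group comparisons (MMSE >= 24 vs < 24) use Kruskal-Wallis tests for
continuous variables and Yates-corrected chi-square tests for 2x2 tables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    EmptyGroupError,
    EnumerationBudgetError,
    MissingMarkerError,
    RankDeficientError,
    TableValidationError,
)

COVARIATES: tuple[str, ...] = ("age", "sex", "education")
MMSE_CUTOFF: int = 24  # scores below indicate significant cognitive deficit


# ---------------------------------------------------------------------------
# transforms and table assembly


def transform_outcome(mmse: np.ndarray) -> np.ndarray:
    """Natural log of MMSE, then z-scored over the cohort.

    A constant vector (SD 0) maps to all-zero scores with a warning; MMSE
    values below 1 are rejected since the log is undefined there.
    """
    mmse = np.asarray(mmse, dtype=float)
    if (mmse < 1).any():
        raise TableValidationError("MMSE scores below 1 cannot be log-transformed")
    logm = np.log(mmse)
    sd = logm.std()
    if sd == 0:
        warnings.warn("constant MMSE vector; log-z scores degenerate to 0")
        return np.zeros_like(logm)
    return (logm - logm.mean()) / sd


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def make_cohort_table(
    marker_table: pd.DataFrame, outcomes: pd.DataFrame
) -> pd.DataFrame:
    """Merge markers and outcomes into the standardized analysis table.

    Marker and covariate columns are z-scored; ``mmse_logz`` holds the
    log-z outcome; ``group`` is True for MMSE >= 24. The marker column list
    travels in ``DataFrame.attrs['markers']``.
    """
    df = marker_table.merge(outcomes, on="subject_id", validate="one_to_one")
    markers = [
        c for c in marker_table.columns
        if c not in ("subject_id", "icv", "incomplete")
    ]
    for col in markers + list(COVARIATES):
        df[col] = zscore(df[col].to_numpy())
    df["mmse_logz"] = transform_outcome(df["mmse"].to_numpy())
    df["group"] = df["mmse"] >= MMSE_CUTOFF
    df.attrs["markers"] = markers
    return df


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class ModelFit:
    """OLS fit of the outcome on a marker subset plus covariates."""

    subset: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    aicc: float
    fvalue: float
    f_pvalue: float
    n: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def aicc_from_rss(n: int, rss: float, k_params: int) -> float:
    """Corrected AIC for a Gaussian model: n ln(RSS/n) + 2k' + 2k'(k'+1)/(n-k'-1)."""
    if n - k_params - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k_params + 2 * k_params * (k_params + 1) / (
        n - k_params - 1
    )


def _design(
    table: pd.DataFrame, subset: tuple[str, ...], covariates: tuple[str, ...]
) -> tuple[pd.DataFrame, np.ndarray]:
    for m in subset:
        if m not in table.columns:
            raise MissingMarkerError(f"marker {m!r} not in table")
    X = table[list(subset) + list(covariates)].astype(float)
    X = sm.add_constant(X, prepend=True)
    y = table["mmse_logz"].to_numpy()
    return X, y


def fit_regression(
    table: pd.DataFrame,
    subset: tuple[str, ...] | list[str],
    covariates: tuple[str, ...] = COVARIATES,
    outcome: str = "mmse_logz",
) -> ModelFit:
    """OLS of the (log-z) outcome on a marker subset, covariates included."""
    subset = tuple(subset)
    X, _ = _design(table, subset, covariates)
    y = table[outcome].to_numpy()
    n, p = X.shape
    if n <= p + 1:
        raise RankDeficientError(f"n={n} too small for {p} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify aliased columns from the pivoted QR diagonal
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise RankDeficientError(f"design is rank deficient; aliased: {aliased}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    return ModelFit(
        subset=subset,
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        aicc=aicc_from_rss(n, rss, p),
        fvalue=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        n=n,
    )


# ---------------------------------------------------------------------------
# univariate screening and intercorrelation


def univariate_screen(
    table: pd.DataFrame,
    markers: list[str] | None = None,
    covariates: tuple[str, ...] = COVARIATES,
) -> pd.DataFrame:
    """Single-marker covariate-adjusted models, one row per marker.

    Reports the marker's standardized slope, its F statistic (squared t of
    the marker term) and p-value, plus the unadjusted Pearson r against the
    outcome.
    """
    markers = markers if markers is not None else table.attrs.get("markers")
    if not markers:
        raise MissingMarkerError("no marker columns specified")
    if len(table) < 10:
        raise TableValidationError("univariate screening needs >= 10 subjects")
    y = table["mmse_logz"].to_numpy()
    rows = []
    for m in markers:
        fit = fit_regression(table, (m,), covariates)
        t = float(fit.tvalues[m])
        rows.append(
            {
                "marker": m,
                "slope": float(fit.params[m]),
                "F": t**2,
                "p": float(fit.pvalues[m]),
                "r_unadjusted": float(np.corrcoef(table[m].to_numpy(), y)[0, 1]),
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def intercorrelation(
    table: pd.DataFrame,
    markers: list[str] | None = None,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-by-marker Pearson matrix with a two-tailed t significance mask.

    t = r sqrt(n-2) / sqrt(1-r^2); the diagonal is 1 and never flagged.
    """
    markers = markers if markers is not None else table.attrs.get("markers")
    n = len(table)
    if n < 3:
        raise TableValidationError("intercorrelation needs >= 3 subjects")
    X = table[markers].to_numpy(dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    corr = (corr + corr.T) / 2.0  # exact symmetry to the last bit
    r = np.clip(corr, -0.999999999999, 0.999999999999)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    sig = (p < alpha) & ~np.eye(len(markers), dtype=bool)
    corr_df = pd.DataFrame(corr, index=markers, columns=markers)
    sig_df = pd.DataFrame(sig, index=markers, columns=markers)
    return corr_df, sig_df


# ---------------------------------------------------------------------------
# all-subset selection


@dataclass
class SelectionResult:
    best: ModelFit
    ranked: list[tuple[tuple[str, ...], float, float]] = field(default_factory=list)
    n_fits: int = 0

    @property
    def best_subset(self) -> tuple[str, ...]:
        return self.best.subset


def _enumerate_size(
    G: np.ndarray,
    b: np.ndarray,
    yty: float,
    n: int,
    base_idx: np.ndarray,
    marker_idx: np.ndarray,
    k: int,
    batch: int = 20000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AICc and RSS of every subset of exactly k markers (batched solves)."""
    combos = np.array(
        list(itertools.combinations(range(len(marker_idx)), k)), dtype=int
    )
    if combos.size == 0 and k > 0:
        return np.zeros((0, k), dtype=int), np.zeros(0), np.zeros(0)
    p = len(base_idx) + k
    ridge = 1e-10 * np.mean(np.diag(G))
    aiccs = np.empty(len(combos) if k else 1)
    rss_all = np.empty_like(aiccs)
    if k == 0:
        idx = base_idx
        beta = np.linalg.solve(G[np.ix_(idx, idx)] + ridge * np.eye(p), b[idx])
        rss = max(yty - beta @ b[idx], 1e-300)
        return (
            np.zeros((1, 0), dtype=int),
            np.array([aicc_from_rss(n, rss, p)]),
            np.array([rss]),
        )
    for start in range(0, len(combos), batch):
        chunk = combos[start : start + batch]
        idx = np.concatenate(
            [np.broadcast_to(base_idx, (len(chunk), len(base_idx))),
             marker_idx[chunk]],
            axis=1,
        )
        Gsub = G[idx[:, :, None], idx[:, None, :]] + ridge * np.eye(p)
        bsub = b[idx]
        beta = np.linalg.solve(Gsub, bsub[..., None])[..., 0]
        rss = np.maximum(yty - (beta * bsub).sum(axis=1), 1e-300)
        kp = p
        with np.errstate(divide="ignore"):
            aiccs[start : start + len(chunk)] = (
                n * np.log(rss / n) + 2 * kp + 2 * kp * (kp + 1) / (n - kp - 1)
                if n - kp - 1 > 0
                else np.inf
            )
        rss_all[start : start + len(chunk)] = rss
    return combos, aiccs, rss_all


def all_subset_select(
    table: pd.DataFrame,
    candidates: list[str] | None = None,
    max_size: int = 8,
    covariates: tuple[str, ...] = COVARIATES,
    top: int = 10,
    fit_budget: int = 10_000_000,
) -> SelectionResult:
    """Exhaustive AICc-ranked search over marker subsets up to ``max_size``.

    Covariates and intercept are always in the model. Ties are broken by
    smaller subset, then lexicographic marker order. Returns the winning
    subset refitted in full detail plus the top-ranked subsets for audit.
    """
    candidates = candidates if candidates is not None else table.attrs.get("markers")
    if not candidates:
        raise MissingMarkerError("no candidate markers specified")
    max_size = min(max_size, len(candidates))
    n_fits = sum(math.comb(len(candidates), k) for k in range(max_size + 1))
    if n_fits > fit_budget:
        raise EnumerationBudgetError(
            f"{n_fits} subset fits exceed the budget of {fit_budget}; "
            "screen candidates first or lower max_size"
        )

    cols = ["__const__"] + list(covariates) + list(candidates)
    A = np.column_stack(
        [np.ones(len(table))]
        + [table[c].to_numpy(dtype=float) for c in covariates]
        + [table[c].to_numpy(dtype=float) for c in candidates]
    )
    y = table["mmse_logz"].to_numpy(dtype=float)
    G = A.T @ A
    b = A.T @ y
    yty = float(y @ y)
    n = len(table)
    base_idx = np.arange(1 + len(covariates))
    marker_idx = np.arange(1 + len(covariates), len(cols))

    tss = float(((y - y.mean()) ** 2).sum())
    entries: list[tuple[float, int, tuple[str, ...], float]] = []
    for k in range(max_size + 1):
        combos, aiccs, rss = _enumerate_size(G, b, yty, n, base_idx, marker_idx, k)
        # keep only the locally best handful per size: global top-N safe
        order = np.argsort(aiccs, kind="stable")[: max(top * 5, 50)]
        for j in order:
            subset = tuple(candidates[i] for i in combos[j])
            r2 = 1.0 - rss[j] / tss if tss > 0 else 0.0
            entries.append((float(aiccs[j]), k, subset, float(r2)))

    entries.sort(key=lambda e: (round(e[0], 9), e[1], e[2]))
    ranked = [(subset, a, r2) for a, _, subset, r2 in entries[:top]]
    best_fit = fit_regression(table, entries[0][2], covariates)
    return SelectionResult(best=best_fit, ranked=ranked, n_fits=n_fits)


# ---------------------------------------------------------------------------
# partial-regression (added-variable) data


def partial_regression_data(
    table: pd.DataFrame,
    fit: ModelFit,
    covariates: tuple[str, ...] = COVARIATES,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Partial-residual pairs per marker, for added-variable plots.

    By Frisch-Waugh-Lovell, the OLS slope through each returned (x, y) pair
    cloud equals that marker's coefficient in the joint model exactly.
    """
    X, y = _design(table, fit.subset, covariates)
    Xm = X.to_numpy()
    out = {}
    for m in fit.subset:
        j = list(X.columns).index(m)
        others = np.delete(Xm, j, axis=1)
        proj = others @ np.linalg.lstsq(others, Xm[:, j], rcond=None)[0]
        x_res = Xm[:, j] - proj
        proj_y = others @ np.linalg.lstsq(others, y, rcond=None)[0]
        y_res = y - proj_y
        out[m] = (x_res, y_res)
    return out


# ---------------------------------------------------------------------------
# demographic / clinical group tests


def chi2_yates(table2x2: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table."""
    obs = np.asarray(table2x2, dtype=float)
    if obs.shape != (2, 2):
        raise TableValidationError("chi2_yates expects a 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=True)
    return float(stat), float(p)


def group_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Compare MMSE >= 24 vs < 24 on age, sex, education and CDR.

    Continuous variables use Kruskal-Wallis; the 2x2 sex and CDR tables use
    the Yates-corrected chi-square.
    """
    g1 = table[table["group"]]
    g0 = table[~table["group"]]
    if len(g1) == 0 or len(g0) == 0:
        raise EmptyGroupError("both MMSE groups must be non-empty")
    rows = []
    for var in ("age", "education"):
        stat, p = stats.kruskal(g1[var], g0[var])
        rows.append({"variable": var, "test": "kruskal-wallis", "stat": stat, "p": p})
    for var in ("sex", "cdr"):
        vals = sorted(table[var].unique())
        if len(vals) != 2:
            raise TableValidationError(
                f"{var!r} must be binary for the 2x2 chi-square, got {vals}"
            )
        tab = np.array(
            [
                [(g1[var] == vals[0]).sum(), (g1[var] == vals[1]).sum()],
                [(g0[var] == vals[0]).sum(), (g0[var] == vals[1]).sum()],
            ]
        )
        stat, p = chi2_yates(tab)
        rows.append({"variable": var, "test": "chi2-yates", "stat": stat, "p": p})
    return pd.DataFrame(rows).set_index("variable")
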