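"""Downstream cohort analyses.

Gestational-age trends (OLS on a restricted-cubic-spline basis with
AIC-selected knot count), Kaplan-Meier curves and Cox models with taxa as
time-varying covariates, beta-defensin-2 group comparisons, Bayesian
two-proportion comparisons with uniform priors, quartile modulation and the
3x3 beta-defensin-2 x Lactobacillus tertile interaction grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import TaxaTable

__all__ = [
    "TrendFit",
    "ProportionComparison",
    "SurvivalResult",
    "GridCell",
    "fit_gestational_trend",
    "km_curve",
    "cox_time_varying",
    "make_intervals",
    "bd2_group_test",
    "beta_binomial_compare",
    "quartile_modulation",
    "interaction_grid",
    "rcs_basis",
    "quantile_bins",
]

log = logging.getLogger(__name__)


def proportion_pct(x: int, n: int, digits: int = 2) -> float:
    """Proportion as a rounded percentage (e.g. 102/521 -> 19.58)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * x / n, digits)


#: Harrell's default knot placement quantiles by knot count.
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
}


# ---------------------------------------------------------------------------
# gestational-age trends
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear in the tails), k-1 columns
    excluding the intercept: x plus k-2 truncated-cubic combinations."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    cols = [x]
    denom = t[-1] - t[0]

    def cub(u):
        return np.maximum(u, 0.0) ** 3

    for j in range(k - 2):
        term = (
            cub(x - t[j])
            - cub(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
            + cub(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        ) / denom**2
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class TrendFit:
    """AIC-selected restricted-cubic-spline OLS trend."""

    n_knots: int
    knots: np.ndarray
    coef: np.ndarray
    aic: float
    r2: float
    sigma: float
    aic_by_knots: dict

    def predict(self, x) -> np.ndarray:
        X = np.column_stack([np.ones(np.size(x)), rcs_basis(np.asarray(x, float), self.knots)])
        return X @ self.coef


def fit_gestational_trend(y, ga, knot_candidates=(3, 4, 5, 6)) -> TrendFit:
    """OLS of y (diversity or log10 bacterial load) on gestational age.

    Fits a restricted-cubic-spline basis with knots at Harrell's standard
    quantiles for each candidate knot count and returns the AIC-minimising
    fit. Collinear candidates (e.g. too few distinct ages) are dropped with
    a warning.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    ga = np.asarray(ga, dtype=float)
    if y.size <= max(knot_candidates) + 2:
        raise ValueError("not enough observations for the largest knot candidate")
    best = None
    aics = {}
    for k in knot_candidates:
        knots = np.quantile(ga, KNOT_QUANTILES[k])
        if np.unique(knots).size < k:
            log.warning("dropping %d-knot candidate: duplicate knot positions", k)
            continue
        X = sm.add_constant(rcs_basis(ga, knots))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            log.warning("dropping %d-knot candidate: collinear basis", k)
            continue
        res = sm.OLS(y, X).fit()
        aics[k] = float(res.aic)
        if best is None or res.aic < best[0]:
            best = (float(res.aic), k, knots, res)
    if best is None:
        raise ValueError("no admissible knot candidate")
    aic, k, knots, res = best
    return TrendFit(
        n_knots=k,
        knots=knots,
        coef=np.asarray(res.params),
        aic=aic,
        r2=float(res.rsquared),
        sigma=float(np.sqrt(res.scale)),
        aic_by_knots=aics,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    hazard_ratio: float
    ci_lo: float
    ci_hi: float
    p: float
    coef: float
    covariate: str = "above_threshold"
    flagged: bool = False
    note: str = ""


def km_curve(time, event, groups):
    """Kaplan-Meier product-limit curves per group plus a Cox p for the
    group contrast (two groups).

    Returns (dict group -> survival DataFrame[time, survival], p or None).
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    if (time <= 0).any():
        raise ValueError("times must be positive")
    curves = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
    p = None
    levels = pd.unique(groups)
    if len(levels) == 2 and event.sum() > 0 and not (groups == levels[0]).all():
        df = pd.DataFrame({"T": time, "E": event, "g": (groups == levels[1]).astype(float)})
        if df.groupby("g")["E"].sum().min() >= 0 and df["g"].nunique() == 2:
            try:
                cph = CoxPHFitter()
                cph.fit(df, duration_col="T", event_col="E")
                p = float(cph.summary.loc["g", "p"])
            except Exception:
                p = None
    return curves, p


def make_intervals(t: TaxaTable, taxon: str, threshold: float) -> pd.DataFrame:
    """Counting-process rows for one taxon's above/below-threshold status.

    Per subject, each visit opens an interval carrying the indicator
    observed at that visit (last observation carried forward); the final
    interval closes at delivery with event=1. Contiguous intervals with the
    same covariate value are collapsed. ``threshold`` is in log10 RA units.
    """
    meta = t.meta
    ra = t.rel_abund[taxon]
    rows = []
    for subj, sub in meta.groupby("subject_id"):
        sub = sub.sort_values("ga_sample")
        if len(sub) == 0:
            log.warning("subject %s has no samples; excluded", subj)
            continue
        ga_del = float(sub["ga_delivery"].iloc[0])
        opens = sub["ga_sample"].to_numpy(dtype=float)
        covs = []
        for sid in sub.index:
            v = ra.loc[sid]
            covs.append(1.0 if (v > 0 and np.log10(v) >= threshold) else 0.0)
        # collapse contiguous equal-covariate intervals
        segs = [[opens[0], covs[0]]]
        for o, c in zip(opens[1:], covs[1:]):
            if c != segs[-1][1]:
                segs.append([o, c])
        for i, (start, c) in enumerate(segs):
            stop = segs[i + 1][0] if i + 1 < len(segs) else ga_del
            if stop <= start:
                continue
            rows.append(
                {
                    "subject_id": subj,
                    "start": start,
                    "stop": stop,
                    "event": int(i + 1 == len(segs)),
                    "covariate": c,
                }
            )
    return pd.DataFrame(rows)


def cox_time_varying(intervals: pd.DataFrame, ties: str = "efron") -> SurvivalResult:
    """Cox model on counting-process rows; HR for the (binary) covariate.

    Maximises the Efron-tie partial likelihood; complete separation or
    non-convergence is reported as a flagged result, not raised.
    """
    from lifelines import CoxTimeVaryingFitter

    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    df = intervals.copy()
    if df["event"].sum() == 0:
        raise ValueError("no events")
    if (df["start"] >= df["stop"]).any():
        raise ValueError("need start < stop in every interval")
    if df["covariate"].nunique() == 1:
        # constant covariate: flat partial likelihood, HR is exactly 1
        return SurvivalResult(
            hazard_ratio=1.0, ci_lo=1.0, ci_hi=1.0, p=1.0, coef=0.0,
            note="constant covariate",
        )
    try:
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            df,
            id_col="subject_id",
            start_col="start",
            stop_col="stop",
            event_col="event",
            formula="covariate",
        )
        s = ctv.summary.loc["covariate"]
        coef = float(s["coef"])
        flagged = abs(coef) > 15  # effectively unbounded -> separation
        return SurvivalResult(
            hazard_ratio=float(np.exp(coef)),
            ci_lo=float(np.exp(s["coef lower 95%"])),
            ci_hi=float(np.exp(s["coef upper 95%"])),
            p=float(s["p"]),
            coef=coef,
            flagged=flagged,
            note="possible separation" if flagged else "",
        )
    except Exception as exc:  # lifelines convergence errors
        return SurvivalResult(
            hazard_ratio=np.nan, ci_lo=np.nan, ci_hi=np.nan, p=np.nan,
            coef=np.nan, flagged=True, note=str(exc),
        )


# ---------------------------------------------------------------------------
# beta-defensin-2 and proportion comparisons
# ---------------------------------------------------------------------------

def bd2_group_test(values, groups, log10: bool = True, welch: bool = True):
    """Two-sample t-test on (log10) beta-defensin-2 levels.

    Returns (mean difference group1 - group2 on the analysed scale, p).
    Welch (unequal variances) by default; a pooled-variance option is kept
    for strict replication. Degenerate (zero-variance, equal) groups short-
    circuit to difference 0, p 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if min(a.size, b.size) < 2:
        raise ValueError("need >= 2 observations per group")
    if log10:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("nonpositive values cannot be log-transformed")
        a, b = np.log10(a), np.log10(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        diff = float(a.mean() - b.mean())
        return diff, (1.0 if diff == 0 else 0.0)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(a.mean() - b.mean()), float(res.pvalue)


@dataclass
class ProportionComparison:
    """Bayesian two-proportion comparison with uniform Beta(1,1) priors."""

    x1: int
    n1: int
    x2: int
    n2: int
    posterior_prob_diff: float  # P(p1 > p2 | data)
    p_value_analog: float  # 2 * min(P, 1-P)


def beta_binomial_compare(x1: int, n1: int, x2: int, n2: int) -> ProportionComparison:
    """P(p1 > p2) under independent Beta(x+1, n-x+1) posteriors.

    Computed by adaptive quadrature of the Beta(x1+1, n1-x1+1) density
    against the Beta(x2+1, n2-x2+1) CDF (high precision, no integer
    restriction on the posterior parameters).
    """
    from scipy.integrate import quad
    from scipy.special import betainc

    for x, n in ((x1, n1), (x2, n2)):
        if not (0 <= x <= n):
            raise ValueError("need 0 <= x <= n")
    a1, b1 = x1 + 1, n1 - x1 + 1
    a2, b2 = x2 + 1, n2 - x2 + 1
    pdf1 = stats.beta(a1, b1).pdf
    val, _ = quad(lambda u: pdf1(u) * betainc(a2, b2, u), 0.0, 1.0, limit=200)
    prob = float(np.clip(val, 0.0, 1.0))
    return ProportionComparison(
        x1=x1, n1=n1, x2=x2, n2=n2,
        posterior_prob_diff=prob,
        p_value_analog=float(max(2.0 * min(prob, 1.0 - prob), 1e-12)),
    )


def quantile_bins(values, n_bins: int) -> np.ndarray:
    """Quantile bins 0..n_bins-1; values tied with an edge fall in the lower
    bin so cuts are reproducible on discrete data."""
    values = np.asarray(values, dtype=float)
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    if np.unique(edges).size < edges.size:
        log.warning("tied quantile edges; bins collapse (tie-aware binning)")
    return np.searchsorted(edges, values, side="left")


def quartile_modulation(bd2, outcome) -> tuple[pd.DataFrame, ProportionComparison]:
    """sPTB proportion within beta-defensin-2 quartiles, over samples where
    the risk taxon of interest was detected (caller pre-filters).

    Returns the per-quartile table and the Q1-vs-Q4 Bayesian comparison.
    """
    bd2 = np.asarray(bd2, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    bins = quantile_bins(bd2, 4)
    rows = []
    for q in range(4):
        mask = bins == q
        n = int(mask.sum())
        xs = int(outcome[mask].sum())
        rows.append(
            {
                "quartile": q + 1,
                "n": n,
                "n_sptb": xs,
                "proportion": xs / n if n else np.nan,
            }
        )
    tab = pd.DataFrame(rows)
    q1, q4 = rows[0], rows[3]
    if q1["n"] == 0 or q4["n"] == 0:
        comp = ProportionComparison(q1["n_sptb"], q1["n"], q4["n_sptb"], q4["n"], np.nan, np.nan)
    else:
        comp = beta_binomial_compare(q1["n_sptb"], q1["n"], q4["n_sptb"], q4["n"])
    return tab, comp


# ---------------------------------------------------------------------------
# 3x3 interaction grid
# ---------------------------------------------------------------------------

@dataclass
class GridCell:
    bd2_tertile: int  # 1..3
    lacto_tertile: int  # 1..3
    n_sptb: int
    n_total: int
    proportion: float
    p_vs_baseline: float
    posterior_prob_higher: float  # P(cell proportion > baseline proportion)
    cst_counts: dict = field(default_factory=dict)
    n_above_threshold: int = 0


def interaction_grid(
    bd2,
    lacto_ra,
    outcome,
    csts=None,
    mcurtisii_ra=None,
    mcurtisii_threshold: float | None = None,
    baseline_x: int = 102,
    baseline_n: int = 521,
) -> list[GridCell]:
    """3x3 tertile grid of beta-defensin-2 x Lactobacillus relative abundance.

    Each cell's sPTB proportion is compared to the study-design baseline
    (default 102/521 = 19.58% at visit 1) with the Bayesian two-proportion
    model. Cells are annotated with their CST composition and the count of
    samples with M. curtisii/mulieris above its risk threshold. Empty cells
    are reported with n=0 and no test.
    """
    bd2 = np.asarray(bd2, dtype=float)
    lac = np.asarray(lacto_ra, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    b_bins = quantile_bins(bd2, 3)
    l_bins = quantile_bins(lac, 3)
    above = None
    if mcurtisii_ra is not None and mcurtisii_threshold is not None:
        mra = np.asarray(mcurtisii_ra, dtype=float)
        with np.errstate(divide="ignore"):
            above = (mra > 0) & (np.log10(np.where(mra > 0, mra, 1.0)) >= mcurtisii_threshold)
    cells = []
    for bt in range(3):
        for lt in range(3):
            mask = (b_bins == bt) & (l_bins == lt)
            n = int(mask.sum())
            xs = int(outcome[mask].sum())
            if n > 0:
                comp = beta_binomial_compare(xs, n, baseline_x, baseline_n)
                p, prob = comp.p_value_analog, comp.posterior_prob_diff
            else:
                p, prob = np.nan, np.nan
            cells.append(
                GridCell(
                    bd2_tertile=bt + 1,
                    lacto_tertile=lt + 1,
                    n_sptb=xs,
                    n_total=n,
                    proportion=xs / n if n else np.nan,
                    p_vs_baseline=p,
                    posterior_prob_higher=prob,
                    cst_counts=(
                        pd.Series(np.asarray(csts)[mask]).value_counts().to_dict()
                        if csts is not None else {}
                    ),
                    n_above_threshold=int(above[mask].sum()) if above is not None else 0,
                )
            )
    return cells


def pool_cells(cells: list[GridCell], bd2_tertiles=None, lacto_tertiles=None,
               baseline_x: int = 102, baseline_n: int = 521) -> ProportionComparison:
    """Compare a pooled set of grid cells (e.g. all high-bd2 cells) to baseline."""
    sel = [
        c
        for c in cells
        if (bd2_tertiles is None or c.bd2_tertile in bd2_tertiles)
        and (lacto_tertiles is None or c.lacto_tertile in lacto_tertiles)
    ]
    xs = sum(c.n_sptb for c in sel)
    n = sum(c.n_total for c in sel)
    return beta_binomial_compare(xs, n, baseline_x, baseline_n)


def grid_frame(cells: list[GridCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bd2_tertile": [c.bd2_tertile for c in cells],
            "lacto_tertile": [c.lacto_tertile for c in cells],
            "n_sptb": [c.n_sptb for c in cells],
            "n_total": [c.n_total for c in cells],
            "proportion": [c.proportion for c in cells],
            "p_vs_baseline": [c.p_vs_baseline for c in cells],
            "n_above_threshold": [c.n_above_threshold for c in cells],
        }
    )
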