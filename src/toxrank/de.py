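"""Per-compound two-step polynomial-regression screen for time-course
differential expression.

The model follows the two-step strategy of time-course microarray screens:

Step 1 (global model). For every gene, fit by ordinary least squares a
polynomial model of (unit-scaled) time with, for every non-control dose
group, a group indicator and indicator x time interactions up to the same
degree. The F-test of this full model against the intercept-only model asks
whether the gene changes over time in at least one experimental group or
shows treatment-dependent expression. F-test p-values are BH-adjusted
across genes and thresholded (default q <= 0.01).

Step 2 (model adjustment). For genes passing step 1, a two-way backward
stepwise regression prunes the model at a Bonferroni-style per-coefficient
threshold alpha = 0.05 / n, n being the number of coefficients of the full
model. A gene is *selected* when it passed step 1, retains at least one
significant treatment-related coefficient (a dose dummy or a dose x time
interaction — time-only trends do not distinguish treatment from control),
and the adjusted (selected) model explains at least 60% of the expression
variance (R^2 >= 0.6).

Degenerate inputs are handled rather than raised: a zero-variance gene gets
p = 1 and R^2 = 0; aliased (rank-deficient) design columns are effectively
dropped by pseudo-inverse fitting and flagged with near-one coefficient
p-values.

A denoising hook is exposed for real-data users who want to plug in a
batch/noise-removal step before fitting; by default it is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import DOSE_LEVELS, ExpressionPanel, SampleMeta
from .stats import bh_fdr

__all__ = [
    "DEParams",
    "DEResult",
    "DesignMatrix",
    "build_design",
    "fit_global",
    "fit_global_matrix",
    "backward_stepwise",
    "StepwiseFit",
    "de_analysis",
    "results_to_frame",
    "frame_to_results",
]


@dataclass(frozen=True)
class DEParams:
    """Screen thresholds.

    max_degree: polynomial degree cap for the time effect (cubic default,
    matching four timepoints). global_fdr: BH-adjusted F-test cut of step 1.
    The stepwise per-coefficient threshold is 0.05 / n with n the number of
    coefficients of the full model. r2_min: minimum variance explained by
    the adjusted model for a gene to count as selected.
    """

    max_degree: int = 3
    global_fdr: float = 0.01
    stepwise_alpha_numerator: float = 0.05
    r2_min: float = 0.6

    def __post_init__(self) -> None:
        if self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        for name in ("global_fdr", "stepwise_alpha_numerator", "r2_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class DEResult:
    """Per-gene outcome of the two-step regression."""

    gene: str
    passed_global: bool
    global_q: float
    adjusted_p: float
    r2: float
    n_coef: int
    has_significant_coef: bool
    selected: bool


@dataclass
class DesignMatrix:
    """A design matrix with named columns and treatment-column bookkeeping."""

    X: np.ndarray
    columns: list[str]
    group_cols: list[int]  # indices of dose dummies and dose:time interactions
    degree: int

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


def build_design(samples: list[SampleMeta], max_degree: int = 3) -> DesignMatrix:
    """Build the global polynomial design for one compound's samples.

    Columns: intercept; time^1..time^d with d = min(max_degree, #distinct
    timepoints - 1); and for every non-control dose level present, a group
    indicator plus indicator x time^1..time^d interactions. Time is scaled
    to unit range for conditioning. Dose levels absent from the samples
    (e.g. a missing low-dose arm) simply contribute no columns.
    """
    times = np.array([s.time for s in samples], dtype=float)
    distinct = np.unique(times)
    if distinct.size < 2:
        raise ValueError("need at least two distinct timepoints")
    if not any(s.dose == "control" for s in samples):
        raise ValueError("no control samples in design")
    d = min(max_degree, distinct.size - 1)
    t = (times - distinct.min()) / (distinct.max() - distinct.min())
    cols: list[np.ndarray] = [np.ones_like(t)]
    names: list[str] = ["intercept"]
    for p in range(1, d + 1):
        cols.append(t**p)
        names.append(f"time^{p}")
    group_cols: list[int] = []
    doses_present = {s.dose for s in samples}
    for dose in DOSE_LEVELS[1:]:
        if dose not in doses_present:
            continue
        ind = np.array([1.0 if s.dose == dose else 0.0 for s in samples])
        group_cols.append(len(cols))
        cols.append(ind)
        names.append(dose)
        for p in range(1, d + 1):
            group_cols.append(len(cols))
            cols.append(ind * t**p)
            names.append(f"{dose}:time^{p}")
    X = np.column_stack(cols)
    return DesignMatrix(X=X, columns=names, group_cols=group_cols, degree=d)


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS via pseudo-inverse; returns (beta, rss, tss, rank, cov_unscaled).

    Aliased columns are absorbed by the pseudo-inverse; their unscaled
    variances blow up, which downstream turns into p ~ 1 so they are pruned
    first by the stepwise pass.
    """
    XtX = X.T @ X
    pinv = np.linalg.pinv(XtX, rcond=1e-10)
    beta = pinv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    yc = y - y.mean()
    tss = float(yc @ yc)
    rank = int(np.linalg.matrix_rank(X, tol=1e-8))
    return beta, rss, tss, rank, pinv


def _f_test(rss: np.ndarray, tss: np.ndarray, rank: int, n: int):
    """F-test of a fitted model against the intercept-only model.

    Returns (p, r2) arrays. Zero-variance responses get p = 1, r2 = 0;
    an exact fit gets p = 0, r2 = 1.
    """
    rss = np.atleast_1d(np.asarray(rss, dtype=float))
    tss = np.atleast_1d(np.asarray(tss, dtype=float))
    df_model = rank - 1
    df_resid = n - rank
    p = np.ones_like(tss)
    r2 = np.zeros_like(tss)
    ok = tss > 0
    if df_model < 1 or df_resid < 1:
        return p, r2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2[ok] = 1.0 - rss[ok] / tss[ok]
    r2 = np.clip(r2, 0.0, 1.0)
    exact = ok & (rss <= 1e-12 * np.maximum(tss, 1.0))
    reg = ok & ~exact
    F = ((tss[reg] - rss[reg]) / df_model) / (rss[reg] / df_resid)
    p[reg] = _sps.f.sf(F, df_model, df_resid)
    p[exact] = 0.0
    return p, r2


def fit_global(y: np.ndarray, design: DesignMatrix) -> tuple[float, dict]:
    """Step-1 fit for one gene: full-model OLS and its F-test p-value.

    Returns (p, fit) where fit carries beta, r2, rss and rank.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.X.shape[0]:
        raise ValueError("response length does not match design rows")
    beta, rss, tss, rank, _ = _ols(y, design.X)
    p, r2 = _f_test(rss, tss, rank, y.size)
    return float(p[0]), {"beta": beta, "r2": float(r2[0]), "rss": rss, "rank": rank}


def fit_global_matrix(Y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized step-1 fits for a gene x sample matrix.

    Returns (p, r2) per gene, with the same conventions as
    :func:`fit_global`.
    """
    Y = np.asarray(Y, dtype=float)
    X = design.X
    n = X.shape[0]
    if Y.shape[1] != n:
        raise ValueError("matrix columns do not match design rows")
    rank = int(np.linalg.matrix_rank(X, tol=1e-8))
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    rss = np.sum(resid * resid, axis=0)
    yc = Y - Y.mean(axis=1, keepdims=True)
    tss = np.sum(yc * yc, axis=1)
    return _f_test(rss, tss, rank, n)


@dataclass
class StepwiseFit:
    """Outcome of the two-way backward stepwise pass for one gene."""

    active: list[int]  # retained column indices into the full design
    beta: np.ndarray
    coef_p: np.ndarray  # per retained coefficient
    r2: float
    model_p: float  # F-test of the selected model vs intercept-only
    alpha: float


def _coef_pvalues(y, Xa, beta, rss, pinv, n):
    k = Xa.shape[1]
    df = n - k
    if df < 1:
        return np.ones(k)
    sigma2 = rss / df
    var = sigma2 * np.clip(np.diag(pinv), 0.0, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(var > 0, beta / np.sqrt(var), 0.0)
    return 2.0 * _sps.t.sf(np.abs(tstat), df)


def backward_stepwise(y: np.ndarray, design: DesignMatrix, alpha: float) -> StepwiseFit:
    """Two-way backward stepwise selection at per-coefficient level alpha.

    Starting from the full model, iteratively drop the coefficient with the
    largest t-test p-value above alpha; after each drop, re-admit any
    excluded variable whose p-value in the current model would be <= alpha
    (two-way). Stops when every retained coefficient is significant or only
    the intercept remains; the intercept is never dropped. A visited-state
    guard prevents add/remove cycles.
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    n, p_full = X.shape
    active = list(range(p_full))
    visited: set[frozenset[int]] = set()
    while True:
        state = frozenset(active)
        if state in visited:
            break
        visited.add(state)
        Xa = X[:, active]
        beta, rss, tss, rank, pinv = _ols(y, Xa)
        pvals = _coef_pvalues(y, Xa, beta, rss, pinv, n)
        # candidates for removal: everything but the intercept (index 0)
        removable = [i for i in range(len(active)) if active[i] != 0]
        if removable:
            worst = max(removable, key=lambda i: pvals[i])
            if pvals[worst] > alpha:
                del active[worst]
                continue
        # two-way: try re-entry of excluded variables
        excluded = [j for j in range(p_full) if j not in active]
        best_j, best_p = None, alpha
        for j in excluded:
            Xtry = X[:, active + [j]]
            b2, rss2, _, _, pinv2 = _ols(y, Xtry)
            p2 = _coef_pvalues(y, Xtry, b2, rss2, pinv2, n)
            if p2[-1] <= best_p and frozenset(active + [j]) not in visited:
                best_j, best_p = j, p2[-1]
        if best_j is not None:
            active = sorted(active + [best_j])
            continue
        break
    Xa = X[:, active]
    beta, rss, tss, rank, pinv = _ols(y, Xa)
    pvals = _coef_pvalues(y, Xa, beta, rss, pinv, n)
    model_p, r2 = _f_test(rss, tss, rank, n)
    if len(active) == 1:  # intercept-only
        model_p, r2 = np.array([1.0]), np.array([0.0])
    return StepwiseFit(
        active=list(active),
        beta=beta,
        coef_p=pvals,
        r2=float(r2[0]),
        model_p=float(model_p[0]),
        alpha=alpha,
    )


def de_analysis(
    panel: ExpressionPanel,
    compound: str,
    params: DEParams = DEParams(),
    denoise=None,
) -> list[DEResult]:
    """Run the two-step screen for one compound, one result per gene.

    ``denoise`` is an optional hook ``f(values, samples) -> values`` applied
    to the compound's expression matrix before fitting (identity when None).
    """
    sub = panel.subset_compound(compound)
    values = sub.values
    if denoise is not None:
        values = np.asarray(denoise(values, sub.samples), dtype=float)
    design = build_design(sub.samples, params.max_degree)

    group_sizes: dict[tuple[str, float], int] = {}
    for s in sub.samples:
        group_sizes[(s.dose, s.time)] = group_sizes.get((s.dose, s.time), 0) + 1
    if min(group_sizes.values()) < 2:
        warnings.warn(
            f"{compound}: fewer than two replicates in some dose/time groups; "
            "proceeding",
            stacklevel=2,
        )

    p_global, _ = fit_global_matrix(values, design)
    q_global = bh_fdr(p_global)
    passed = q_global <= params.global_fdr
    alpha = params.stepwise_alpha_numerator / design.n_coef
    group_col_set = set(design.group_cols)

    results: list[DEResult] = []
    for gi, gene in enumerate(sub.gene_ids):
        if not passed[gi]:
            results.append(
                DEResult(
                    gene=gene,
                    passed_global=False,
                    global_q=float(q_global[gi]),
                    adjusted_p=1.0,
                    r2=0.0,
                    n_coef=design.n_coef,
                    has_significant_coef=False,
                    selected=False,
                )
            )
            continue
        fit = backward_stepwise(values[gi], design, alpha)
        has_sig = any(c in group_col_set for c in fit.active)
        selected = bool(has_sig and fit.r2 >= params.r2_min)
        results.append(
            DEResult(
                gene=gene,
                passed_global=True,
                global_q=float(q_global[gi]),
                adjusted_p=fit.model_p,
                r2=fit.r2,
                n_coef=design.n_coef,
                has_significant_coef=has_sig,
                selected=selected,
            )
        )
    return results


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "passed_global": [int(r.passed_global) for r in results],
            "global_q": [r.global_q for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "r2": [r.r2 for r in results],
            "n_coef": [r.n_coef for r in results],
            "has_significant_coef": [int(r.has_significant_coef) for r in results],
            "selected": [int(r.selected) for r in results],
        }
    )


def frame_to_results(df: pd.DataFrame) -> list[DEResult]:
    return [
        DEResult(
            gene=str(row.gene),
            passed_global=bool(row.passed_global),
            global_q=float(row.global_q),
            adjusted_p=float(row.adjusted_p),
            r2=float(row.r2),
            n_coef=int(row.n_coef),
            has_significant_coef=bool(row.has_significant_coef),
            selected=bool(row.selected),
        )
        for row in df.itertuples(index=False)
    ]
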