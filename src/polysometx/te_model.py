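"""Per-gene negative-binomial GLM and the knockdown x fraction test.

Each gene's counts are modeled as negative binomial (variance mu + phi*mu^2)
with a log link,

    log mu = offset + intercept + cell line + replicate
             + gamma*KD + delta*POLY + theta*KD*POLY,

where the offset is the log effective (TMM-scaled) library size. The
interaction coefficient theta captures a knockdown-induced shift of the
polysome:total ratio, i.e. a change in translational efficiency; the null
hypothesis theta = 0 is tested per gene by a likelihood-ratio chi-square
with 1 degree of freedom (a Wald test is available as an alternative).

Coefficients are fitted by iteratively reweighted least squares (IRLS) with
step-halving on the log-likelihood, at a fixed dispersion; at phi = 0 the
fit reduces exactly to Poisson regression. Dispersions are estimated from
the Cox-Reid adjusted profile likelihood (APL): a common value by grid
search with golden-section refinement, an abundance trend from a moving
window of the per-gene APLs along mean log-CPM, and tagwise values by
empirical-Bayes shrinkage toward the trend (weighted likelihood with
prior weight prior_df / residual df).

All fitting is vectorized across genes: every gene shares the design
matrix, so the per-iteration normal equations are solved as a batch of
small p x p systems.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, false_discovery_control

from .io import CountMatrix, SampleDesign, ValidationError, align_design
from .normalize import NormFactors, cpm, filter_expressed, tmm_factors

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "NBFit",
    "DispersionEstimates",
    "build_design",
    "fit_nb_glm",
    "fit_nb_glm_batch",
    "nb_loglik",
    "estimate_dispersions",
    "lrt_interaction",
    "run_te_test",
]

_PHI_POISSON = 1e-8  # below this, the Poisson likelihood is used


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Full and reduced (no-interaction) model matrices for one experiment."""

    full: np.ndarray
    reduced: np.ndarray
    columns: list[str]
    interaction_index: int
    sample_ids: list[str]

    @property
    def n_params_full(self) -> int:
        return self.full.shape[1]


def _first_seen_levels(values: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def build_design(designs: Sequence[SampleDesign]) -> DesignMatrix:
    """Treatment-coded design for the interaction model.

    Reference levels are control, total, and the first-seen cell line and
    replicate. Columns: intercept, cell-line dummies, replicate dummies,
    knockdown, polysome (fraction), knockdown x polysome. Raises on a
    rank-deficient design and names the confounded columns.
    """
    conditions = {d.condition for d in designs}
    fractions = {d.fraction for d in designs}
    if conditions != {"control", "knockdown"}:
        raise ValidationError(
            f"design needs both control and knockdown samples; saw {sorted(conditions)}"
        )
    if fractions != {"total", "polysome"}:
        raise ValidationError(
            f"design needs both total and polysome samples; saw {sorted(fractions)}"
        )

    cells = _first_seen_levels([d.cell_line for d in designs])
    reps = _first_seen_levels([d.replicate for d in designs])
    cols: list[np.ndarray] = [np.ones(len(designs))]
    names = ["intercept"]
    for cl in cells[1:]:
        cols.append(np.array([1.0 if d.cell_line == cl else 0.0 for d in designs]))
        names.append(f"cell_line[{cl}]")
    for r in reps[1:]:
        cols.append(np.array([1.0 if d.replicate == r else 0.0 for d in designs]))
        names.append(f"replicate[{r}]")
    kd = np.array([1.0 if d.condition == "knockdown" else 0.0 for d in designs])
    poly = np.array([1.0 if d.fraction == "polysome" else 0.0 for d in designs])
    cols += [kd, poly, kd * poly]
    names += ["knockdown", "fraction[polysome]", "knockdown:fraction"]

    full = np.column_stack(cols)
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        # identify columns that are linear combinations of earlier ones
        dependent = []
        for j in range(1, full.shape[1]):
            if np.linalg.matrix_rank(full[:, : j + 1]) <= np.linalg.matrix_rank(full[:, :j]):
                dependent.append(names[j])
        raise ValidationError(
            f"rank-deficient design (rank {rank} < {full.shape[1]}); "
            f"confounded column(s): {dependent}"
        )
    interaction_index = full.shape[1] - 1
    reduced = full[:, :interaction_index]
    return DesignMatrix(
        full=full,
        reduced=reduced,
        columns=names,
        interaction_index=interaction_index,
        sample_ids=[d.sample_id for d in designs],
    )


# ---------------------------------------------------------------------------
# Likelihood and batched IRLS
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Row-wise NB log-likelihood (variance mu + phi*mu^2); phi may be per-row.

    ``y`` and ``mu`` are (G, n); ``phi`` is scalar or (G,). Rows with
    phi < 1e-8 use the Poisson limit.
    """
    y = np.atleast_2d(y)
    mu = np.atleast_2d(mu)
    phi_arr = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float)), (y.shape[0],))
    out = np.empty(y.shape[0])
    pois = phi_arr < _PHI_POISSON
    if np.any(pois):
        m = mu[pois]
        out[pois] = np.sum(y[pois] * np.log(m) - m - gammaln(y[pois] + 1.0), axis=1)
    if np.any(~pois):
        r = 1.0 / phi_arr[~pois][:, None]
        m = mu[~pois]
        yy = y[~pois]
        out[~pois] = np.sum(
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1.0)
            + r * np.log(r / (r + m))
            + yy * np.log(m / (r + m)),
            axis=1,
        )
    return out


@dataclass
class NBFit:
    """Result of a (possibly batched) NB GLM fit at fixed dispersion."""

    coef: np.ndarray  # (G, p)
    mu: np.ndarray  # (G, n)
    loglik: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    usable: np.ndarray  # (G,) bool; False for degenerate (all-zero) genes
    phi: np.ndarray  # (G,)

    def single(self) -> "NBFitView":
        return NBFitView(
            coef=self.coef[0],
            mu=self.mu[0],
            loglik=float(self.loglik[0]),
            converged=bool(self.converged[0]),
            usable=bool(self.usable[0]),
            phi=float(self.phi[0]),
        )


@dataclass
class NBFitView:
    """One gene's fit (convenience unpacking of a batch of size 1)."""

    coef: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    usable: bool
    phi: float


_ETA_MAX = 50.0  # exp(50) ~ 5e21; keeps mu finite


def fit_nb_glm_batch(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    phi: np.ndarray | float = 0.0,
    beta_init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> NBFit:
    """Fit one NB GLM per row of ``Y`` by IRLS with step-halving.

    All rows share the design ``X`` (n x p) and per-sample ``offset``.
    ``phi`` is a scalar or per-row vector; phi = 0 gives exact Poisson
    regression. Convergence: relative log-likelihood change < ``tol``.
    All-zero rows are returned flagged unusable (coefficients at a floor).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    p = X.shape[1]
    if np.any(Y < 0):
        raise ValidationError("counts must be non-negative")
    phi_arr = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float)), (G,)).copy()
    if np.any(phi_arr < 0):
        raise ValidationError("dispersion must be non-negative")
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    if offset.ndim == 1:
        offset = np.broadcast_to(offset, (G, n))

    usable = Y.sum(axis=1) > 0

    if beta_init is None:
        # working init: regress log(y + 0.5) - offset on X (unweighted)
        z0 = np.log(Y + 0.5) - offset
        beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    else:
        beta = np.array(beta_init, dtype=float, copy=True)
        if beta.ndim == 1:
            beta = np.broadcast_to(beta, (G, p)).copy()

    def mu_of(b: np.ndarray) -> np.ndarray:
        eta = b @ X.T + offset
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    mu = mu_of(beta)
    ll = nb_loglik(Y, mu, phi_arr)
    converged = np.zeros(G, dtype=bool)
    active = usable.copy()

    for _ in range(max_iter):
        if not np.any(active):
            break
        idx = np.flatnonzero(active)
        mu_a = mu[idx]
        phi_a = phi_arr[idx][:, None]
        w = mu_a / (1.0 + phi_a * mu_a)  # working weights, (g, n)
        eta_a = np.log(mu_a)
        z = (eta_a - offset[idx]) + (Y[idx] - mu_a) / mu_a  # working response
        Xw = X[None, :, :] * w[:, :, None]  # (g, n, p)
        XtWX = np.einsum("gnp,nq->gpq", Xw, X)
        XtWz = np.einsum("gnp,gn->gp", Xw, z)
        # ridge jitter for near-singular systems (extreme weights)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - jitter should prevent
            beta_new = np.array(
                [np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0] for g in range(len(idx))]
            )
        # step-halving on the log-likelihood
        step = beta_new - beta[idx]
        ll_old = ll[idx]
        frac = np.ones(len(idx))
        cand = beta[idx] + step
        for _half in range(12):
            mu_c = np.exp(np.clip(cand @ X.T + offset[idx], -_ETA_MAX, _ETA_MAX))
            ll_c = nb_loglik(Y[idx], mu_c, phi_arr[idx])
            worse = ll_c < ll_old - 1e-12
            if not np.any(worse):
                break
            frac = np.where(worse, frac / 2.0, frac)
            cand = beta[idx] + frac[:, None] * step
        beta[idx] = cand
        mu[idx] = np.exp(np.clip(cand @ X.T + offset[idx], -_ETA_MAX, _ETA_MAX))
        ll_new = nb_loglik(Y[idx], mu[idx], phi_arr[idx])
        rel = np.abs(ll_new - ll_old) / (np.abs(ll_old) + 1.0)
        done = rel < tol
        converged[idx[done]] = True
        ll[idx] = ll_new
        active[idx[done]] = False

    # degenerate rows: floor the mean, flag unusable
    if np.any(~usable):
        beta[~usable] = 0.0
        beta[~usable, 0] = -_ETA_MAX
        mu[~usable] = np.exp(
            np.clip(beta[~usable] @ X.T + offset[~usable], -_ETA_MAX, _ETA_MAX)
        )
        ll[~usable] = nb_loglik(Y[~usable], mu[~usable], phi_arr[~usable])
        converged[~usable] = False

    return NBFit(coef=beta, mu=mu, loglik=ll, converged=converged, usable=usable, phi=phi_arr)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    phi: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> NBFitView:
    """Fit a single gene's NB GLM (see :func:`fit_nb_glm_batch`)."""
    fit = fit_nb_glm_batch(
        np.asarray(y, dtype=float)[None, :], X, offset=offset, phi=phi, tol=tol,
        max_iter=max_iter,
    )
    return fit.single()


def _cr_adjustment(mu: np.ndarray, phi: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cox-Reid adjustment 0.5*logdet(X'WX) per row."""
    w = mu / (1.0 + phi[:, None] * mu)
    Xw = X[None, :, :] * w[:, :, None]
    XtWX = np.einsum("gnp,nq->gpq", Xw, X) + 1e-10 * np.eye(X.shape[1])[None, :, :]
    sign, logdet = np.linalg.slogdet(XtWX)
    return 0.5 * logdet


def _apl(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    beta_init: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Cox-Reid adjusted profile log-likelihood at one dispersion."""
    fit = fit_nb_glm_batch(Y, X, offset=offset, phi=phi, beta_init=beta_init)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (Y.shape[0],))
    apl = fit.loglik - _cr_adjustment(fit.mu, phi_arr, X)
    apl = np.where(fit.usable, apl, np.nan)
    return apl, fit.coef


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimates:
    """Common, trended and tagwise NB dispersions."""

    common: float
    trend: pd.Series
    tagwise: pd.Series
    prior_df: float
    avg_log_cpm: pd.Series = field(repr=False, default=None)


def _golden_max(fun, lo: float, hi: float, tol: float = 1e-3, max_iter: int = 40) -> float:
    """Golden-section maximization of ``fun`` over log-dispersion [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return (a + b) / 2.0


def _parabolic_argmax(log_grid: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Row-wise quadratic-interpolated argmax of ``vals`` over ``log_grid``."""
    G, K = vals.shape
    j = np.nanargmax(vals, axis=1)
    j = np.clip(j, 1, K - 2)
    x0, x1, x2 = log_grid[j - 1], log_grid[j], log_grid[j + 1]
    rows = np.arange(G)
    y0, y1, y2 = vals[rows, j - 1], vals[rows, j], vals[rows, j + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom
    shift = np.where(np.isfinite(shift), np.clip(shift, -1.0, 1.0), 0.0)
    step = x1 - x0
    est = x1 + shift * step
    # genes whose maximum sits on the grid edge stay at the edge value
    edge_lo = np.nanargmax(vals, axis=1) == 0
    edge_hi = np.nanargmax(vals, axis=1) == K - 1
    est = np.where(edge_lo, log_grid[0], est)
    est = np.where(edge_hi, log_grid[-1], est)
    return est


def _moving_mean(sorted_vals: np.ndarray, half_window: int) -> np.ndarray:
    """Centered moving average along axis 0 with truncated edges."""
    n = sorted_vals.shape[0]
    cs = np.nancumsum(np.vstack([np.zeros((1, sorted_vals.shape[1])), sorted_vals]), axis=0)
    counts = np.cumsum(
        np.concatenate([[0], (~np.isnan(sorted_vals[:, 0])).astype(float)])
    )
    lo = np.maximum(np.arange(n) - half_window, 0)
    hi = np.minimum(np.arange(n) + half_window + 1, n)
    sums = cs[hi] - cs[lo]
    cnt = (counts[hi] - counts[lo])[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        return sums / np.maximum(cnt, 1.0)


def estimate_dispersions(
    cm: CountMatrix,
    design: DesignMatrix,
    nf: NormFactors,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
    min_genes_for_trend: int = 50,
) -> DispersionEstimates:
    """Estimate common, trended and tagwise dispersions by Cox-Reid APL.

    The common value maximizes the summed APL over a log-spaced grid with
    golden-section refinement. The trend is, per gene, the maximizer of a
    moving-window mean of the APL curves along average log-CPM. Tagwise
    values maximize APL_g + prior_n * (window-mean APL) with prior_n =
    prior_df / residual df; prior_df -> infinity recovers the trend. With
    fewer than ``min_genes_for_trend`` genes, trend and tagwise fall back to
    the common value (with a warning).
    """
    X = design.full
    n, p = X.shape
    if n - p < 2:
        raise ValidationError(f"needs >= 2 residual df; design has {n - p}")
    Y = cm.values.astype(float)
    G = Y.shape[0]
    offset = np.log(nf.effective_lib_sizes.loc[list(cm.sample_ids)].to_numpy())
    if grid is None:
        grid = np.geomspace(1e-4, 10.0, 19)
    log_grid = np.log(grid)

    # APL matrix over the grid, warm-starting along the sweep
    apl = np.empty((G, len(grid)))
    beta = None
    for k, ph in enumerate(grid):
        apl[:, k], beta = _apl(Y, X, offset, float(ph), beta)
    usable = ~np.isnan(apl[:, 0])
    n_use = int(usable.sum())
    if n_use == 0:
        raise ValidationError("no usable genes (all rows zero)")

    # common dispersion: grid + golden-section refinement
    total = np.nansum(apl, axis=0)
    k0 = int(np.argmax(total))
    lo = log_grid[max(k0 - 1, 0)]
    hi = log_grid[min(k0 + 1, len(grid) - 1)]

    def common_obj(log_phi: float) -> float:
        vals, _ = _apl(Y[usable], X, offset, float(np.exp(log_phi)), None)
        return float(np.nansum(vals))

    common = float(np.exp(_golden_max(common_obj, lo, hi))) if lo < hi else float(grid[k0])

    gene_index = cm.gene_ids
    mean_cpm = (Y / np.exp(offset)[None, :] * 1e6).mean(axis=1)
    avg_log_cpm = pd.Series(np.log2(mean_cpm + 0.5), index=gene_index, name="avg_log_cpm")

    if n_use < min_genes_for_trend:
        warnings.warn(
            f"only {n_use} usable genes; falling back to common dispersion",
            stacklevel=2,
        )
        trend = pd.Series(np.full(G, common), index=gene_index, name="trend")
        tagwise = trend.copy()
        tagwise.name = "tagwise"
        return DispersionEstimates(common, trend, tagwise, prior_df, avg_log_cpm)

    # trend: moving-window mean APL along abundance, per-gene argmax
    order = np.argsort(avg_log_cpm.to_numpy(), kind="stable")
    apl_sorted = apl[order]
    half_window = max(50, n_use // 10)
    shared_sorted = _moving_mean(np.where(np.isnan(apl_sorted), np.nan, apl_sorted), half_window)
    shared = np.empty_like(shared_sorted)
    shared[order] = shared_sorted
    log_trend = _parabolic_argmax(log_grid, np.where(np.isnan(shared), -np.inf, shared))
    trend_vals = np.exp(log_trend)

    # tagwise: weighted likelihood APL_g + prior_n * shared
    prior_n = prior_df / max(n - p, 1)
    obj = np.where(np.isnan(apl), -np.inf, apl) + prior_n * np.where(
        np.isnan(shared), -np.inf, shared
    )
    log_tag = _parabolic_argmax(log_grid, obj)
    tag_vals = np.exp(log_tag)
    # degenerate genes inherit the trend at their abundance
    tag_vals = np.where(usable, tag_vals, trend_vals)

    trend = pd.Series(trend_vals, index=gene_index, name="trend")
    tagwise = pd.Series(tag_vals, index=gene_index, name="tagwise")
    return DispersionEstimates(common, trend, tagwise, prior_df, avg_log_cpm)


# ---------------------------------------------------------------------------
# Interaction test
# ---------------------------------------------------------------------------


def lrt_interaction(
    ll_full: np.ndarray | float, ll_reduced: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Likelihood-ratio statistic and p-value (chi-square, 1 df).

    Tiny negative statistics (>= -1e-6) are clipped to 0; anything more
    negative is flagged as a numerical failure (p = NaN).
    """
    stat = 2.0 * (np.asarray(ll_full, dtype=float) - np.asarray(ll_reduced, dtype=float))
    stat = np.atleast_1d(stat)
    failed = stat < -1e-6
    stat = np.where(stat < 0, 0.0, stat)
    p = chi2.sf(stat, df=1)
    p = np.where(failed, np.nan, p)
    stat = np.where(failed, np.nan, stat)
    return stat, p, failed


def run_te_test(
    cm: CountMatrix,
    designs: Sequence[SampleDesign],
    p_threshold: float = 0.05,
    min_cpm: float = 2.0,
    min_sample_frac: float = 0.5,
    prior_df: float = 10.0,
    test: str = "lrt",
) -> pd.DataFrame:
    """Full per-gene pipeline: TMM -> dispersions -> GLM fits -> interaction test.

    Returns a table with, per gene: the interaction estimate ``theta_hat``
    (natural-log scale), the test statistic and raw p-value, a
    Benjamini-Hochberg ``q_value`` (reported, not used for nomination),
    average log2 CPM, the ``expressed`` flag (CPM > ``min_cpm`` in >=
    ``min_sample_frac`` of libraries) and ``nominated`` = significant AND
    expressed. Genes with unusable fits (all-zero counts) carry missing
    p-values and are never nominated.
    """
    if test not in ("lrt", "wald"):
        raise ValidationError("test must be 'lrt' or 'wald'")
    designs = align_design(cm, designs)
    dm = build_design(designs)
    nf = tmm_factors(cm)
    cpm_mat = cpm(cm, nf)
    expressed = filter_expressed(cpm_mat, min_cpm=min_cpm, min_sample_frac=min_sample_frac)
    disp = estimate_dispersions(cm, dm, nf, prior_df=prior_df)

    Y = cm.values.astype(float)
    offset = np.log(nf.effective_lib_sizes.loc[list(cm.sample_ids)].to_numpy())
    phi = disp.tagwise.to_numpy()
    fit_full = fit_nb_glm_batch(Y, dm.full, offset=offset, phi=phi)
    theta_hat = fit_full.coef[:, dm.interaction_index]

    if test == "lrt":
        fit_red = fit_nb_glm_batch(Y, dm.reduced, offset=offset, phi=phi)
        stat, p, failed = lrt_interaction(fit_full.loglik, fit_red.loglik)
    else:
        w = fit_full.mu / (1.0 + phi[:, None] * fit_full.mu)
        Xw = dm.full[None, :, :] * w[:, :, None]
        XtWX = np.einsum("gnp,nq->gpq", Xw, dm.full) + 1e-10 * np.eye(dm.full.shape[1])
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(cov[:, dm.interaction_index, dm.interaction_index])
        stat = (theta_hat / se) ** 2
        p = chi2.sf(stat, df=1)
        failed = ~np.isfinite(stat)

    usable = fit_full.usable
    p = np.where(usable, p, np.nan)
    stat = np.where(usable, stat, np.nan)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = false_discovery_control(p[ok], method="bh")

    table = pd.DataFrame(
        {
            "theta_hat": np.where(usable, theta_hat, np.nan),
            "lrt_stat" if test == "lrt" else "wald_stat": stat,
            "p_value": p,
            "q_value": q,
            "avg_log_cpm": disp.avg_log_cpm,
            "dispersion": phi,
            "expressed": expressed.to_numpy(),
            "usable": usable,
        },
        index=cm.gene_ids,
    )
    table["nominated"] = (
        np.isfinite(p) & (p < p_threshold) & table["expressed"] & table["usable"]
    )
    return table
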