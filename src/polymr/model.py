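"""Polynomial Mendelian randomization with a polynomial control function.

The estimator is two-stage least squares with a control function: the
exposure x is first regressed on the instruments G jointly,

    β̂ = (G'G)⁻¹ G'x,

and the outcome is then regressed on powers of the exposure together with
powers of the first-stage residual,

    y ~ 1 + x + ... + x^k + (x − Gβ̂) + ... + (x − Gβ̂)^l.

The residual powers absorb confounding and reverse causation that is
correlated with the exposure (k = l = 1 recovers the textbook control
function / 2SLS estimate), so the retained exposure coefficients α̂_j
estimate the causal polynomial. Backward selection drops non-significant
higher-order exposure terms at a Bonferroni-corrected level, residual
powers are truncated to the highest surviving exposure order, and
non-linearity is judged by a likelihood ratio test against the model with
only the linear exposure term but the same residual-correction columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import lstsq as _scipy_lstsq

logger = logging.getLogger(__name__)

__all__ = [
    "PolyMR",
    "PolyMRResults",
    "FirstStageFit",
    "CausalCurve",
    "CollinearityError",
    "DegenerateInputError",
    "InsufficientSampleError",
    "standardize",
    "fit_first_stage",
    "build_design",
    "fit_polymr",
    "filter_ivs_reverse",
    "standardized_marginal_betas",
    "reverse_filter_indices",
]

CONDITION_WARN = 1e8


class CollinearityError(ValueError):
    """Design or instrument matrix is (numerically) rank deficient."""


class DegenerateInputError(ValueError):
    """Input with no variation where variation is required."""


class InsufficientSampleError(ValueError):
    """Fewer samples than design columns."""


def standardize(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Center and scale to sample mean 0, variance 1.

    Returns ``(z, mean, sd)`` so the original scale can be restored as
    ``z * sd + mean``. Raises :class:`DegenerateInputError` for a constant
    vector.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise DegenerateInputError("need at least 2 values to standardize")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (v - mean) / sd, mean, sd


@dataclass
class FirstStageFit:
    """Joint OLS of the exposure on all instruments.

    ``residual_exposure`` (x − Gβ̂) is the in-sample estimate of the
    non-genetic exposure component ε_x used as the control function basis.
    """

    beta_hat: np.ndarray
    fitted_exposure: np.ndarray
    residual_exposure: np.ndarray


def fit_first_stage(G: np.ndarray, x: np.ndarray) -> FirstStageFit:
    """Estimate instrument effects by joint least squares (no intercept;
    inputs are centered), solved by orthogonal decomposition."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    x = np.asarray(x, dtype=float)
    if G.ndim != 2 or G.shape[0] != x.shape[0]:
        raise ValueError("G must be an n×m matrix row-aligned with x")
    n, m = G.shape
    if m == 0:
        raise ValueError("empty instrument set: no SNP passed selection")
    if n <= m:
        raise InsufficientSampleError(f"need n > m instruments ({n} samples, {m} SNPs)")
    beta, _, rank, _ = _scipy_lstsq(G, x, cond=1e-10, lapack_driver="gelsy")
    if rank < m:
        # identify offending columns from the pivoted QR diagonal
        r_diag = np.abs(np.diag(np.linalg.qr(G, mode="r")))
        bad = np.flatnonzero(r_diag < r_diag.max() * np.finfo(float).eps * max(n, m))
        raise CollinearityError(
            f"instrument matrix is rank deficient (rank {rank} < {m}); "
            f"offending columns: {bad.tolist()}"
        )
    fitted = G @ beta
    return FirstStageFit(beta_hat=beta, fitted_exposure=fitted, residual_exposure=x - fitted)


def _design_columns(
    x: np.ndarray,
    residual: np.ndarray,
    exp_orders: list[int],
    res_orders: list[int],
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Design [1, x^j for j in exp_orders, e^j for j in res_orders]."""
    n = x.shape[0]
    cols = [np.ones(n)]
    names: list[tuple[str, int]] = [("const", 0)]
    for j in exp_orders:
        cols.append(x**j)
        names.append(("x", j))
    for j in res_orders:
        cols.append(residual**j)
        names.append(("e", j))
    return np.column_stack(cols), names


def build_design(
    x: np.ndarray, fitted_exposure: np.ndarray, k: int, l: int
) -> np.ndarray:
    """Second-stage design [1, x, ..., x^k, (x−Gβ̂), ..., (x−Gβ̂)^l]."""
    if k < 1:
        raise ValueError("k must be at least 1: the linear term is the model floor")
    if l < 0:
        raise ValueError("l must be non-negative")
    x = np.asarray(x, dtype=float)
    residual = x - np.asarray(fitted_exposure, dtype=float)
    M, _ = _design_columns(x, residual, list(range(1, k + 1)), list(range(1, l + 1)))
    return M


@dataclass
class _SubmodelFit:
    """Classical OLS results for one column subset of a fixed design."""

    cols: list[int]
    params: np.ndarray
    cov: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    rss: float
    df_resid: int
    llf: float
    rsquared: float


class _ProjectedOLS:
    """Every candidate submodel of one fixed design, via a single thin QR.

    With M = QR, the OLS problem y ~ M[:, S] reduces to the p-dimensional
    problem Q'y ~ R[:, S] plus the constant residual of y outside the
    column space of M, so each backward-elimination refit costs O(p³)
    instead of O(np²). Solutions are numerically identical to a direct
    orthogonal-decomposition fit of the subset.
    """

    def __init__(self, M: np.ndarray, y: np.ndarray):
        n, p = M.shape
        if n <= p:
            raise InsufficientSampleError(f"{n} samples for {p} design columns")
        self.n = n
        Q, self.R = np.linalg.qr(M)
        cond = np.linalg.cond(self.R)
        if cond > CONDITION_WARN:
            warnings.warn(
                f"design condition number {cond:.2e} exceeds {CONDITION_WARN:.0e}; "
                "estimates may be numerically unstable",
                RuntimeWarning,
                stacklevel=3,
            )
        self.qty = Q.T @ y
        # residual sum of squares outside the full column space
        self.rss_outside = float(y @ y - self.qty @ self.qty)
        self.tss = float(((y - y.mean()) ** 2).sum())

    def fit(self, cols: list[int]) -> _SubmodelFit:
        Rs = self.R[:, cols]
        beta, _, rank, _ = np.linalg.lstsq(Rs, self.qty, rcond=None)
        if rank < len(cols):
            raise CollinearityError(f"singular design with columns {cols}")
        small_resid = self.qty - Rs @ beta
        rss = self.rss_outside + float(small_resid @ small_resid)
        df_resid = self.n - len(cols)
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.inv(Rs.T @ Rs)
        cov = sigma2 * xtx_inv
        bse = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / bse
        pvalues = 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)
        # Gaussian log-likelihood with the error variance profiled out
        llf = -self.n / 2.0 * (np.log(2.0 * np.pi * rss / self.n) + 1.0)
        return _SubmodelFit(
            cols=list(cols),
            params=beta,
            cov=cov,
            bse=bse,
            pvalues=pvalues,
            rss=rss,
            df_resid=df_resid,
            llf=float(llf),
            rsquared=1.0 - rss / self.tss,
        )


@dataclass
class CausalCurve:
    """Estimated causal function on an exposure grid, anchored so the curve
    is 0 at the mean exposure, with a pointwise 95% confidence hull obtained
    from multivariate-normal coefficient draws."""

    grid: np.ndarray
    estimate: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    n_draws: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.grid,
                "estimate": self.estimate,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        )


@dataclass
class PolyMRResults:
    """Fitted PolyMR model.

    Coefficients refer to the internally standardized exposure and outcome;
    :meth:`causal_curve` maps back to the input scales. ``alpha`` maps the
    retained exposure power j to α̂_j, ``r`` maps residual powers to r̂_j.
    """

    model: "PolyMR"
    alpha: dict[int, float]
    r: dict[int, float]
    intercept: float
    params: np.ndarray
    coef_cov: np.ndarray
    coef_names: list[tuple[str, int]]
    pvalues: np.ndarray
    bse: np.ndarray
    nonlinearity_p: float
    causal_r2: float
    loglik_full: float
    loglik_linear: float
    n_samples: int
    selection_trace: list[tuple[int, float]]
    residual_noise: np.ndarray = field(repr=False)
    first_stage: FirstStageFit = field(repr=False)

    @property
    def k_retained(self) -> int:
        """Highest retained exposure order."""
        return max(self.alpha) if self.alpha else 0

    @property
    def exposure_orders(self) -> list[int]:
        return sorted(self.alpha)

    def alpha_or_zero(self, order: int) -> float:
        """α̂_j, with eliminated coefficients counted as 0."""
        return self.alpha.get(order, 0.0)

    def cov_params(self) -> pd.DataFrame:
        labels = [f"{kind}^{j}" if kind != "const" else "const" for kind, j in self.coef_names]
        return pd.DataFrame(self.coef_cov, index=labels, columns=labels)

    def coefficient_table(self) -> pd.DataFrame:
        labels, kinds, orders = [], [], []
        for kind, j in self.coef_names:
            labels.append("const" if kind == "const" else f"{kind}^{j}")
            kinds.append(kind)
            orders.append(j)
        return pd.DataFrame(
            {
                "term": labels,
                "kind": kinds,
                "order": orders,
                "estimate": self.params,
                "se": self.bse,
                "p": self.pvalues,
            }
        )

    def causal_curve(
        self,
        grid: np.ndarray | None = None,
        n_draws: int = 10_000,
        seed: int | np.random.Generator | None = None,
    ) -> CausalCurve:
        """Causal polynomial on ``grid`` (default: percentiles 1–99 of the
        observed exposure) with a pointwise 95% hull.

        The point estimate and every coefficient draw are anchored to 0 at
        the mean exposure, so the hull reflects uncertainty in the *shape*
        of the curve, not its level.
        """
        mdl = self.model
        if grid is None:
            grid = np.percentile(mdl.exposure_orig, np.arange(1, 100))
        grid = np.asarray(grid, dtype=float)
        z = (grid - mdl.x_mean) / mdl.x_sd

        orders = self.exposure_orders
        if orders:
            Z = np.column_stack([z**j for j in orders])  # anchored: z=0 at mean
            a = np.array([self.alpha[j] for j in orders])
            est = Z @ a
        else:
            Z = np.zeros((grid.size, 0))
            est = np.zeros(grid.size)

        if n_draws < 100:
            raise ValueError("n_draws must be at least 100")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = [i for i, (kind, j) in enumerate(self.coef_names) if kind == "x"]
        cov = self.coef_cov[np.ix_(idx, idx)]
        mean = self.params[idx]
        try:
            draws = rng.multivariate_normal(mean, cov, size=n_draws, method="cholesky")
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh((cov + cov.T) / 2.0)
            w = np.clip(w, 0.0, None)  # PSD repair by eigenvalue clipping
            draws = mean + rng.standard_normal((n_draws, w.size)) @ (np.sqrt(w)[:, None] * V.T)
        curves = draws @ Z.T if orders else np.zeros((n_draws, grid.size))
        lower = np.percentile(curves, 2.5, axis=0)
        upper = np.percentile(curves, 97.5, axis=0)

        y_sd = mdl.y_sd
        return CausalCurve(
            grid=grid,
            estimate=est * y_sd,
            lower95=lower * y_sd,
            upper95=upper * y_sd,
            n_draws=n_draws,
        )

    def summary(self) -> str:
        lines = [
            "PolyMR results",
            "=" * 62,
            f"n samples:            {self.n_samples}",
            f"instruments used:     {self.model.n_instruments}"
            + (
                f" (of {self.model.n_instruments_initial} before reverse-causation filter)"
                if self.model.n_instruments_initial != self.model.n_instruments
                else ""
            ),
            f"exposure orders:      {self.exposure_orders or '[]'}",
            f"residual orders:      {sorted(self.r) or '[]'}",
            f"non-linearity p:      {self.nonlinearity_p:.4g}",
            f"causally explained r2: {self.causal_r2:.4g}",
            "-" * 62,
            f"{'term':>8} {'estimate':>12} {'se':>12} {'p':>12}",
        ]
        for row in self.coefficient_table().itertuples():
            lines.append(f"{row.term:>8} {row.estimate:>12.6g} {row.se:>12.6g} {row.p:>12.4g}")
        if self.selection_trace:
            dropped = ", ".join(f"x^{j} (p={p:.3g})" for j, p in self.selection_trace)
            lines.append("-" * 62)
            lines.append(f"eliminated: {dropped}")
        lines.append("=" * 62)
        return "\n".join(lines)


class PolyMR:
    """Polynomial MR model of a continuous outcome on a continuous exposure,
    instrumented by genotype dosages.

    Parameters
    ----------
    outcome, exposure
        Length-n phenotype vectors; standardized internally.
    genotypes
        n×m instrument dosage matrix (standardized internally per column).
    k_max, l_max
        Highest exposure and residual-correction powers in the initial
        design (both default 10).
    instrument_p_threshold
        If given, instruments are pre-filtered by their marginal association
        with the exposure at this two-sided p threshold.
    reverse_filter
        Drop instruments whose standardized marginal effect on the outcome
        exceeds (in absolute value) their effect on the exposure — a guard
        against instruments acting through reverse causation.
    missing
        "drop" removes rows with any missing value (count logged);
        "raise" errors on missing data.
    genotypes_standardized
        Set True when every genotype column is already mean 0 / variance 1
        (e.g. output of the built-in simulator) to skip re-standardizing
        the dosage matrix.
    """

    def __init__(
        self,
        outcome: np.ndarray,
        exposure: np.ndarray,
        genotypes: np.ndarray,
        k_max: int = 10,
        l_max: int = 10,
        instrument_p_threshold: float | None = None,
        reverse_filter: bool = True,
        missing: str = "drop",
        genotypes_standardized: bool = False,
    ):
        y = np.asarray(outcome, dtype=float).ravel()
        x = np.asarray(exposure, dtype=float).ravel()
        G = np.atleast_2d(np.asarray(genotypes, dtype=float))
        if G.shape[0] != x.shape[0] or y.shape[0] != x.shape[0]:
            raise ValueError("outcome, exposure and genotypes must be row-aligned")
        if k_max < 1:
            raise ValueError("k_max must be at least 1")
        if l_max < 0:
            raise ValueError("l_max must be non-negative")

        ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(G).all(axis=1)
        if not ok.all():
            if missing == "raise":
                raise ValueError(f"{int((~ok).sum())} rows contain missing values")
            logger.info("dropping %d rows with missing values", int((~ok).sum()))
            y, x, G = y[ok], x[ok], G[ok]

        self.k_max = k_max
        self.l_max = l_max
        self.exposure_orig = x
        self.outcome_orig = y
        x_std, self.x_mean, self.x_sd = standardize(x)
        y_std, self.y_mean, self.y_sd = standardize(y)
        if genotypes_standardized:
            G_std = G
        else:
            g_sd = G.std(axis=0)
            if np.any(g_sd == 0.0):
                bad = np.flatnonzero(g_sd == 0.0)
                raise DegenerateInputError(f"monomorphic genotype columns: {bad.tolist()}")
            G_std = (G - G.mean(axis=0)) / g_sd

        n = x_std.shape[0]
        # marginal SNP-trait correlations (= standardized marginal betas)
        b_exp = G_std.T @ x_std / n
        kept = np.arange(G.shape[1])
        if instrument_p_threshold is not None:
            from .simulate import correlation_pvalues

            kept = np.flatnonzero(correlation_pvalues(b_exp, n) < instrument_p_threshold)
            logger.info(
                "instrument selection at p<%g: %d of %d SNPs retained",
                instrument_p_threshold, kept.size, G.shape[1],
            )
        self.n_instruments_initial = kept.size
        if reverse_filter and kept.size:
            b_out = G_std[:, kept].T @ y_std / n
            sub = filter_ivs_reverse(b_exp[kept], b_out)
            logger.info(
                "reverse-causation filter: %d of %d instruments retained",
                sub.size, kept.size,
            )
            kept = kept[sub]
        self.instrument_indices = kept
        self.n_instruments = kept.size
        self._x = x_std
        self._y = y_std
        self._G = G_std[:, kept]

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        exposure: str,
        outcome: str,
        snp_columns: "list[str] | None" = None,
        **kwargs,
    ) -> "PolyMR":
        """Build from a tidy DataFrame; ``snp_columns`` defaults to every
        column other than the exposure and outcome."""
        if snp_columns is None:
            snp_columns = [c for c in data.columns if c not in (exposure, outcome)]
        for col in (exposure, outcome, *snp_columns):
            if col not in data.columns:
                raise KeyError(f"column {col!r} not in data; available: {list(data.columns)}")
        return cls(
            data[outcome].to_numpy(float),
            data[exposure].to_numpy(float),
            data[snp_columns].to_numpy(float),
            **kwargs,
        )

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        select: bool = True,
        alpha_level: float = 0.05,
        l1: bool = False,
        robust: bool = False,
    ) -> PolyMRResults:
        """Fit the control-function polynomial regression.

        With ``select=True`` (default), exposure coefficients of order ≥ 2
        are eliminated backwards, one per iteration (the least significant
        among those with p ≥ alpha_level/k_max), truncating residual powers
        to the highest surviving exposure order after each removal. The
        intercept and the linear term are never candidates. ``l1=True`` is
        the PolyMR-L1 variant: a single first-order residual-correction term
        with truncation disabled.
        """
        if self._G.shape[1] == 0:
            raise ValueError("empty instrument set: nothing to fit")
        x, y = self._x, self._y
        first = fit_first_stage(self._G, x)
        resid = first.residual_exposure

        k, l = self.k_max, (1 if l1 else self.l_max)
        bonferroni = alpha_level / self.k_max
        exp_orders = list(range(1, k + 1))
        res_orders = list(range(1, l + 1))
        M_full, names_full = _design_columns(x, resid, exp_orders, res_orders)
        col_of = {name: i for i, name in enumerate(names_full)}
        proj = _ProjectedOLS(M_full, y)

        def cols_for(eo: list[int], ro: list[int]) -> list[int]:
            return [0] + [col_of[("x", j)] for j in eo] + [col_of[("e", j)] for j in ro]

        trace: list[tuple[int, float]] = []
        while True:
            fitted = proj.fit(cols_for(exp_orders, res_orders))
            if not select:
                break
            cand = [
                (j, fitted.pvalues[1 + idx])
                for idx, j in enumerate(exp_orders)
                if j >= 2 and fitted.pvalues[1 + idx] >= bonferroni
            ]
            if not cand:
                break
            # drop the highest-order non-significant term: adjacent powers of
            # the exposure are strongly collinear, and removing lower orders
            # first lets their signal migrate into spurious higher orders
            j_drop, p_drop = max(cand, key=lambda jp: jp[0])
            trace.append((j_drop, float(p_drop)))
            logger.debug("eliminating x^%d (p=%.3g)", j_drop, p_drop)
            exp_orders.remove(j_drop)
            if not l1:
                res_orders = list(range(1, min(self.l_max, max(exp_orders)) + 1))

        names = [("const", 0)] + [("x", j) for j in exp_orders] + [("e", j) for j in res_orders]

        # non-linearity LRT: linear exposure term only, residual columns frozen
        df_nl = sum(1 for j in exp_orders if j >= 2)
        if df_nl > 0:
            llf_lin = proj.fit(cols_for([1], res_orders)).llf
            lr = 2.0 * (fitted.llf - llf_lin)
            nonlin_p = float(stats.chi2.sf(max(lr, 0.0), df=df_nl))
        else:
            llf_lin = fitted.llf
            nonlin_p = 1.0

        # causally explained variance: drop all exposure-power columns
        confounder_only = proj.fit(cols_for([], res_orders))
        causal_r2 = float(np.clip(fitted.rsquared - confounder_only.rsquared, 0.0, 1.0))

        M_final = M_full[:, fitted.cols]
        residual_noise = y - M_final @ fitted.params
        cov, bse, pvalues = fitted.cov, fitted.bse, fitted.pvalues
        if robust:
            # HC0 sandwich on the final model; selection and LRT stay classical
            xtx_inv = fitted.cov * (fitted.df_resid / fitted.rss)
            meat = (M_final * residual_noise[:, None] ** 2).T @ M_final
            cov = xtx_inv @ meat @ xtx_inv
            bse = np.sqrt(np.diag(cov))
            pvalues = 2.0 * stats.norm.sf(np.abs(fitted.params / bse))

        alpha = {j: float(fitted.params[i]) for i, (kind, j) in enumerate(names) if kind == "x"}
        r = {j: float(fitted.params[i]) for i, (kind, j) in enumerate(names) if kind == "e"}
        return PolyMRResults(
            model=self,
            alpha=alpha,
            r=r,
            intercept=float(fitted.params[0]),
            params=np.asarray(fitted.params),
            coef_cov=np.asarray(cov),
            coef_names=names,
            pvalues=np.asarray(pvalues),
            bse=np.asarray(bse),
            nonlinearity_p=nonlin_p,
            causal_r2=causal_r2,
            loglik_full=fitted.llf,
            loglik_linear=llf_lin,
            n_samples=x.shape[0],
            selection_trace=trace,
            residual_noise=residual_noise,
            first_stage=first,
        )


def fit_polymr(
    G: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    l: int = 10,
    select: bool = True,
    alpha_level: float = 0.05,
    l1: bool = False,
    **model_kwargs,
) -> PolyMRResults:
    """Functional one-call interface: build a :class:`PolyMR` model and fit.

    ``l1=True`` fits the PolyMR-L1 variant (first-order control function).
    Instrument pre-filtering is off by default here; pass
    ``instrument_p_threshold=...`` / ``reverse_filter=True`` to enable.
    """
    model_kwargs.setdefault("reverse_filter", False)
    model = PolyMR(y, x, G, k_max=k, l_max=l, **model_kwargs)
    return model.fit(select=select, alpha_level=alpha_level, l1=l1)


def standardized_marginal_betas(G: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """Marginal simple-regression slopes of a standardized trait on each
    standardized SNP (equal to the per-SNP Pearson correlations)."""
    G = np.asarray(G, dtype=float)
    t = np.asarray(trait, dtype=float)
    n = t.shape[0]
    tc = t - t.mean()
    # G' tc equals the centered cross product because tc sums to zero
    num = G.T @ tc
    css = (G**2).sum(axis=0) - n * G.mean(axis=0) ** 2
    return num / np.sqrt(css * (tc @ tc))


def filter_ivs_reverse(
    std_beta_exposure: np.ndarray, std_beta_outcome: np.ndarray
) -> np.ndarray:
    """Indices of instruments whose standardized effect on the outcome does
    not exceed, in absolute value, their effect on the exposure.

    Instruments with a larger outcome effect plausibly act on the exposure
    through the outcome (reverse causation) and are removed; the boundary
    case of equal magnitudes is retained.
    """
    b_exp = np.asarray(std_beta_exposure, dtype=float)
    b_out = np.asarray(std_beta_outcome, dtype=float)
    if b_exp.shape != b_out.shape:
        raise ValueError("effect vectors must have equal length")
    return np.flatnonzero(np.abs(b_out) <= np.abs(b_exp))


def reverse_filter_indices(G: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Apply the reverse-causation instrument filter from raw data."""
    return filter_ivs_reverse(
        standardized_marginal_betas(G, x), standardized_marginal_betas(G, y)
    )
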