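"""Replicate simulation study: bias, RMSE and confidence-interval calibration.

Each replicate simulates a dataset, selects genome-wide-significant
instruments, fits the estimator, and evaluates the anchored causal curve on
a common grid of exposure percentiles (the percentiles of the standard
normal, since the simulated exposure is standardized and curves are
anchored at the mean). Per-replicate seeds are derived deterministically
from the master seed and the replicate index, so results do not depend on
execution order and replicates can be distributed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import PolyMR
from .simulate import SimulationSettings, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateSummary",
    "run_replicates",
    "bias_curve",
    "rmse_curve",
    "ci_calibration",
    "replicate_seed",
    "PERCENTILES",
]

#: Exposure percentiles at which curves are evaluated.
PERCENTILES = np.arange(1, 100)


def percentile_grid() -> np.ndarray:
    """Standard-normal quantiles at the evaluation percentiles."""
    return stats.norm.ppf(PERCENTILES / 100.0)


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed, independent of execution order."""
    return int(np.random.SeedSequence([master_seed, replicate]).generate_state(1)[0] % (2**31))


def bias_curve(estimates: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Mean over replicates of (anchored estimate − anchored truth), per
    grid point. Anchoring makes this level-free: a constant offset common to
    estimate and truth cancels."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    truth = np.asarray(truth, dtype=float)
    if estimates.shape[1] != truth.shape[0]:
        raise ValueError(
            f"grid mismatch: estimates have {estimates.shape[1]} points, "
            f"truth has {truth.shape[0]}"
        )
    return estimates.mean(axis=0) - truth


def rmse_curve(
    estimates: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Per-grid-point RMSE over replicates, plus the scenario summary.

    Returns ``(rmse_per_point, mean_rmse, (ci_low, ci_high))`` where the
    scenario mean is the average over replicates of each replicate's
    whole-grid RMSE, with a 95% normal-approximation CI of that mean.
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    truth = np.asarray(truth, dtype=float)
    if estimates.shape[1] != truth.shape[0]:
        raise ValueError("grid mismatch between estimates and truth")
    err = estimates - truth
    per_point = np.sqrt((err**2).mean(axis=0))
    per_rep = np.sqrt((err**2).mean(axis=1))
    mean_rmse = float(per_rep.mean())
    half = 1.96 * per_rep.std(ddof=1) / np.sqrt(per_rep.size) if per_rep.size > 1 else np.inf
    return per_point, mean_rmse, (mean_rmse - half, mean_rmse + half)


def ci_calibration(
    estimates: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    truth: np.ndarray,
) -> pd.DataFrame:
    """Compare predicted and empirical uncertainty at each grid point.

    Predicted width is the mean hull width (upper − lower); empirical width
    is the 2.5–97.5 inter-percentile range of the point estimates across
    replicates; coverage is the fraction of replicates whose hull contains
    the anchored truth.
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    lower = np.atleast_2d(np.asarray(lower, dtype=float))
    upper = np.atleast_2d(np.asarray(upper, dtype=float))
    truth = np.asarray(truth, dtype=float)
    if not (estimates.shape == lower.shape == upper.shape):
        raise ValueError("estimates, lower and upper must share a shape")
    if estimates.shape[1] != truth.shape[0]:
        raise ValueError("grid mismatch between estimates and truth")
    if estimates.shape[0] < 20:
        warnings.warn(
            "fewer than 20 replicates: empirical widths and coverage are "
            "highly uncertain",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "predicted_width": (upper - lower).mean(axis=0),
            "empirical_width": np.percentile(estimates, 97.5, axis=0)
            - np.percentile(estimates, 2.5, axis=0),
            "coverage": ((lower <= truth) & (truth <= upper)).mean(axis=0),
        }
    )


@dataclass
class ReplicateSummary:
    """Aggregated metrics for one scenario × method combination."""

    scenario_id: str
    method: str
    n_replicates: int
    n_skipped: int
    percentiles: np.ndarray
    grid: np.ndarray
    mean_bias: np.ndarray
    rmse: np.ndarray
    mean_rmse: float
    mean_rmse_ci: tuple[float, float]
    predicted_ci_width: np.ndarray | None
    empirical_ci_width: np.ndarray | None
    coverage: np.ndarray | None
    detection: dict[int, int]
    mean_alpha: dict[int, float]
    estimates: np.ndarray = field(repr=False)
    truth: np.ndarray = field(repr=False)
    alpha_by_order: dict[int, np.ndarray] = field(repr=False)
    nonlinearity_p: np.ndarray = field(repr=False)
    causal_r2: np.ndarray = field(repr=False)
    n_instruments: np.ndarray = field(repr=False)

    def metrics_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "percentile": self.percentiles,
                "exposure": self.grid,
                "truth": self.truth,
                "mean_bias": self.mean_bias,
                "rmse": self.rmse,
            }
        )
        if self.predicted_ci_width is not None:
            out["predicted_ci_width"] = self.predicted_ci_width
            out["empirical_ci_width"] = self.empirical_ci_width
            out["coverage"] = self.coverage
        return out

    def summary(self) -> str:
        det = ", ".join(f"order {k}: {v}" for k, v in sorted(self.detection.items()))
        ma = ", ".join(f"a{k}={v:.4g}" for k, v in sorted(self.mean_alpha.items()) if v != 0.0)
        lines = [
            f"scenario:        {self.scenario_id} ({self.method})",
            f"replicates:      {self.n_replicates} completed, {self.n_skipped} skipped",
            f"mean RMSE:       {self.mean_rmse:.5g} "
            f"(95% CI {self.mean_rmse_ci[0]:.5g}..{self.mean_rmse_ci[1]:.5g})",
            f"highest order:   {det}",
            f"mean alpha:      {ma or 'all zero'}",
            f"mean instruments: {self.n_instruments.mean():.1f}",
        ]
        return "\n".join(lines)


def run_replicates(
    settings: SimulationSettings,
    n_reps: int,
    method: str = "polymr",
    seed: int = 0,
    n_draws: int = 1_000,
    compute_hulls: bool = True,
    select: bool = True,
    scenario_id: str | None = None,
) -> ReplicateSummary:
    """Run the full simulate → instrument selection → fit → curve pipeline
    ``n_reps`` times and aggregate.

    ``method`` is ``"polymr"`` (full control function, l = k) or
    ``"polymr_l1"`` (first-order control function). Replicates whose
    instrument selection returns an empty set are skipped with a warning and
    counted in ``n_skipped``. With ``compute_hulls=False`` the per-replicate
    confidence hulls (the slowest step) are not drawn and the CI-calibration
    columns are None.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    if method not in ("polymr", "polymr_l1"):
        raise ValueError("method must be 'polymr' or 'polymr_l1'")
    l1 = method == "polymr_l1"

    z = percentile_grid()
    f = settings.causal_function
    truth = f(z) - f(np.zeros(1))[0]

    est_rows, lo_rows, hi_rows = [], [], []
    alpha_rows: list[dict[int, float]] = []
    nl_p, cr2, n_iv, highest = [], [], [], []
    skipped = 0

    for rep in range(n_reps):
        rep_seed = replicate_seed(seed, rep)
        data = simulate_dataset(settings.with_(seed=rep_seed))
        model = PolyMR(
            data.outcome_raw,
            data.exposure,
            data.genotypes,
            k_max=10,
            l_max=10,
            instrument_p_threshold=settings.gwas_p_threshold,
            reverse_filter=True,
            genotypes_standardized=True,
        )
        if model.n_instruments == 0:
            skipped += 1
            logger.warning("replicate %d: no instrument passed selection; skipped", rep)
            continue
        res = model.fit(select=select, l1=l1)

        # common z-grid mapped to this replicate's raw exposure scale
        grid_raw = z * model.x_sd + model.x_mean
        if compute_hulls:
            curve = res.causal_curve(
                grid_raw, n_draws=n_draws, seed=np.random.default_rng(rep_seed + 1)
            )
            est, lo, hi = curve.estimate, curve.lower95, curve.upper95
        else:
            a = np.array([res.alpha[j] for j in res.exposure_orders])
            Z = np.column_stack([z**j for j in res.exposure_orders])
            est = (Z @ a) * model.y_sd
            lo = hi = None
        est_rows.append(est)
        if compute_hulls:
            lo_rows.append(lo)
            hi_rows.append(hi)
        alpha_rows.append(res.alpha)
        nl_p.append(res.nonlinearity_p)
        cr2.append(res.causal_r2)
        n_iv.append(model.n_instruments)
        highest.append(res.k_retained)

    if len(est_rows) < 2:
        raise RuntimeError(
            f"only {len(est_rows)} of {n_reps} replicates completed; "
            "cannot aggregate"
        )
    estimates = np.vstack(est_rows)
    mean_bias = bias_curve(estimates, truth)
    rmse, mean_rmse, rmse_ci = rmse_curve(estimates, truth)

    if compute_hulls:
        calib = ci_calibration(estimates, np.vstack(lo_rows), np.vstack(hi_rows), truth)
        pred_w = calib["predicted_width"].to_numpy()
        emp_w = calib["empirical_width"].to_numpy()
        cov = calib["coverage"].to_numpy()
    else:
        pred_w = emp_w = cov = None

    orders = range(1, 11)
    alpha_by_order = {
        j: np.array([a.get(j, 0.0) for a in alpha_rows]) for j in orders
    }
    detection: dict[int, int] = {}
    for h in highest:
        detection[h] = detection.get(h, 0) + 1

    return ReplicateSummary(
        scenario_id=scenario_id or "custom",
        method=method,
        n_replicates=len(est_rows),
        n_skipped=skipped,
        percentiles=PERCENTILES.copy(),
        grid=z,
        mean_bias=mean_bias,
        rmse=rmse,
        mean_rmse=mean_rmse,
        mean_rmse_ci=rmse_ci,
        predicted_ci_width=pred_w,
        empirical_ci_width=emp_w,
        coverage=cov,
        detection=detection,
        mean_alpha={j: float(v.mean()) for j, v in alpha_by_order.items()},
        estimates=estimates,
        truth=truth,
        alpha_by_order=alpha_by_order,
        nonlinearity_p=np.array(nl_p),
        causal_r2=np.array(cr2),
        n_instruments=np.array(n_iv),
    )
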