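"""Synthetic genotype–exposure–outcome data under a confounded causal model.

The generative model is

    X = G·β + q_x·U + ε_x
    Y = f(X) + q_y·U + q_y2·U² + ε_y

with a standard-normal confounder U, standardized genotype columns G whose
minor allele frequencies follow Beta(1, 3), and per-SNP effects
β_i ~ N(0, (p_i(1−p_i))^−0.25) rescaled so Σβ_i² = h². The exposure noise
variance is 1 − h² − q_x² so that Var(X) = 1 by construction; the outcome
noise variance is, by default, chosen so that Var(Y) = 1 as well.

The causal function f may be polynomial, exponential, signed square root,
or sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CausalFunction",
    "SimulationSettings",
    "SimulatedDataset",
    "simulate_genotypes",
    "draw_effect_sizes",
    "evaluate_causal_function",
    "simulate_dataset",
    "select_instruments",
    "marginal_gwas_pvalues",
    "SCENARIOS",
    "get_scenario",
]

MAF_MIN = 0.01
MAF_MAX = 0.5

_FAMILIES = ("polynomial", "exponential", "signed_sqrt", "sigmoid")


@dataclass(frozen=True)
class CausalFunction:
    """Shape of the causal effect of the exposure on the outcome.

    Parameters
    ----------
    family
        One of ``polynomial``, ``exponential``, ``signed_sqrt``, ``sigmoid``.
    coefficients
        For the polynomial family, the coefficients (α_0, α_1, ..., α_k) in
        increasing order. Ignored for other families.
    scale
        Prefactor for the non-polynomial families, e.g. ``scale * exp(x)``.
    steepness
        Exponent multiplier of the sigmoid: ``scale / (1 + exp(-steepness*x))``.
    """

    family: str = "polynomial"
    coefficients: tuple[float, ...] = (0.0,)
    scale: float = 0.1
    steepness: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown causal function family {self.family!r}; "
                f"expected one of {_FAMILIES}"
            )
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if self.family == "polynomial" and len(self.coefficients) == 0:
            raise ValueError("polynomial causal function needs at least one coefficient")
        if not np.isfinite(self.scale):
            raise ValueError("scale must be finite")
        if self.family == "sigmoid" and not self.steepness > 0:
            raise ValueError("sigmoid steepness must be positive")

    @classmethod
    def polynomial(cls, *coefficients: float) -> "CausalFunction":
        """Polynomial f(x) = Σ c_j x^j from coefficients in increasing order."""
        return cls(family="polynomial", coefficients=tuple(coefficients))

    @property
    def is_null(self) -> bool:
        return self.family == "polynomial" and not any(self.coefficients)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return evaluate_causal_function(self, x)


def evaluate_causal_function(spec: CausalFunction, x: np.ndarray) -> np.ndarray:
    """Evaluate f(x) elementwise for any causal-function family."""
    x = np.asarray(x, dtype=float)
    if spec.family == "polynomial":
        # Horner in increasing-coefficient convention
        return np.polynomial.polynomial.polyval(x, np.asarray(spec.coefficients))
    if spec.family == "exponential":
        return spec.scale * np.exp(x)
    if spec.family == "signed_sqrt":
        return spec.scale * np.sign(x) * np.sqrt(np.abs(x))
    if spec.family == "sigmoid":
        return spec.scale / (1.0 + np.exp(-spec.steepness * x))
    raise ValueError(f"unknown causal function family {spec.family!r}")


@dataclass(frozen=True)
class SimulationSettings:
    """Every generative parameter of one simulation scenario.

    ``q_x``, ``q_y`` and ``q_y2`` are the confounder weights on the exposure
    and on the linear/quadratic outcome terms. ``outcome_noise_sd=None``
    (default) balances the outcome noise so Var(Y) = 1; a float fixes the
    noise standard deviation instead.
    """

    n_samples: int = 100_000
    n_causal_snps: int = 100
    heritability: float = 0.5
    q_x: float = 0.2
    q_y: float = 0.5
    q_y2: float = 0.0
    causal_function: CausalFunction = field(
        default_factory=lambda: CausalFunction.polynomial(0.0, 0.1, 0.05)
    )
    gwas_p_threshold: float = 5e-8
    outcome_noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_causal_snps < 1:
            raise ValueError("n_causal_snps must be at least 1")
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        if self.heritability + self.q_x**2 >= 1.0:
            raise ValueError(
                "heritability + q_x^2 must be < 1 so the exposure noise "
                "variance is positive"
            )
        if not 0.0 < self.gwas_p_threshold < 1.0:
            raise ValueError("gwas_p_threshold must lie in (0, 1)")

    def with_(self, **kwargs) -> "SimulationSettings":
        """Copy with fields replaced (scenario variations)."""
        return replace(self, **kwargs)


@dataclass
class SimulatedDataset:
    """One realized dataset plus every latent component, for diagnostics.

    ``exposure`` is the raw G·β + q_x·U + ε_x; ``exposure_std`` is its
    empirically standardized copy, which is what the causal function was
    applied to when generating the outcome. ``outcome`` is standardized to
    mean 0 / variance 1; ``outcome_raw`` is kept on its natural scale.
    """

    genotypes: np.ndarray
    mafs: np.ndarray
    true_beta: np.ndarray
    confounder: np.ndarray
    exposure: np.ndarray
    exposure_std: np.ndarray
    outcome: np.ndarray
    outcome_raw: np.ndarray
    exposure_noise: np.ndarray
    outcome_noise: np.ndarray
    settings: SimulationSettings

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def true_curve(self, grid: np.ndarray, anchor: float = 0.0) -> np.ndarray:
        """True causal function on ``grid``, anchored to 0 at ``anchor``."""
        f = self.settings.causal_function
        return f(np.asarray(grid, dtype=float)) - f(np.asarray(anchor, dtype=float))


def simulate_genotypes(
    n: int, m: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an n×m matrix of standardized biallelic dosages.

    MAFs are Beta(1, 3) draws resampled into [0.01, 0.5]; raw dosages are
    Binomial(2, p) per SNP; each column is standardized to mean 0, variance 1.
    Monomorphic columns (possible at small n) are redrawn.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 samples and m >= 1 SNPs")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    mafs = rng.beta(1.0, 3.0, size=m)
    bad = (mafs < MAF_MIN) | (mafs > MAF_MAX)
    while bad.any():
        mafs[bad] = rng.beta(1.0, 3.0, size=int(bad.sum()))
        bad = (mafs < MAF_MIN) | (mafs > MAF_MAX)

    # Binomial(2, p) as the sum of two Bernoulli layers, generated SNP-major
    # so per-SNP reductions are contiguous; the result is returned as an
    # n×m (Fortran-order) view without a transpose copy.
    p = mafs[:, None]
    raw = np.add(
        rng.random((m, n)) < p, rng.random((m, n)) < p, dtype=np.int8
    )
    sd = raw.std(axis=1)
    degenerate = sd == 0.0
    while degenerate.any():
        rows = np.flatnonzero(degenerate)
        raw[rows] = rng.binomial(2, mafs[rows, None], size=(rows.size, n)).astype(np.int8)
        sd[rows] = raw[rows].std(axis=1)
        degenerate = sd == 0.0

    G = (raw - raw.mean(axis=1)[:, None]) / sd[:, None]
    return G.T, mafs


def draw_effect_sizes(
    mafs: np.ndarray, h2: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Per-SNP effects β_i ~ N(0, (p_i(1−p_i))^−0.25), rescaled to Σβ² = h².

    The MAF-dependent term is read as the variance of the draw; any constant
    factor is absorbed by the rescaling.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size == 0:
        raise ValueError("empty MAF vector")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    if not 0.0 < h2 < 1.0:
        raise ValueError("heritability must lie in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sd = (mafs * (1.0 - mafs)) ** -0.125
    beta = rng.normal(0.0, sd)
    return beta * np.sqrt(h2 / np.sum(beta**2))


def simulate_dataset(settings: SimulationSettings) -> SimulatedDataset:
    """Generate one full dataset under ``settings``.

    Deterministic given ``settings.seed``: independent sub-streams are spawned
    for genotypes, effect sizes, the confounder and the two noise terms, so
    each component can be varied independently of the others.
    """
    ss = np.random.SeedSequence(settings.seed)
    rng_g, rng_b, rng_u, rng_ex, rng_ey = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    n, m, h2 = settings.n_samples, settings.n_causal_snps, settings.heritability
    G, mafs = simulate_genotypes(n, m, rng_g)
    beta = draw_effect_sizes(mafs, h2, rng_b)

    U = rng_u.standard_normal(n)
    eps_x_var = 1.0 - h2 - settings.q_x**2
    eps_x = rng_ex.standard_normal(n) * np.sqrt(eps_x_var)
    x_raw = G @ beta + settings.q_x * U + eps_x
    # the causal function acts on an exactly unit-variance exposure
    x_std = (x_raw - x_raw.mean()) / x_raw.std()

    signal = (
        settings.causal_function(x_std)
        + settings.q_y * U
        + settings.q_y2 * U**2
    )
    if settings.outcome_noise_sd is None:
        noise_var = max(1.0 - signal.var(), 0.05)
        noise_sd = float(np.sqrt(noise_var))
    else:
        noise_sd = float(settings.outcome_noise_sd)
    eps_y = rng_ey.standard_normal(n) * noise_sd
    y_raw = signal + eps_y
    y_std = (y_raw - y_raw.mean()) / y_raw.std()

    return SimulatedDataset(
        genotypes=G,
        mafs=mafs,
        true_beta=beta,
        confounder=U,
        exposure=x_raw,
        exposure_std=x_std,
        outcome=y_std,
        outcome_raw=y_raw,
        exposure_noise=eps_x,
        outcome_noise=eps_y,
        settings=settings,
    )


def marginal_gwas_pvalues(G: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two-sided p values of the marginal regression of x on each SNP.

    Classical simple-regression t test, computed from the per-SNP Pearson
    correlation: t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    G = np.asarray(G, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    xc = x - x.mean()
    # G' xc equals the centered cross product because xc sums to zero
    num = G.T @ xc
    css = (G**2).sum(axis=0) - n * G.mean(axis=0) ** 2
    r = num / np.sqrt(css * (xc @ xc))
    return correlation_pvalues(r, n)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p values of Pearson correlations via the exact t transform
    t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def select_instruments(
    dataset_or_G: "SimulatedDataset | np.ndarray",
    exposure: np.ndarray | None = None,
    p_threshold: float = 5e-8,
) -> np.ndarray:
    """Indices of SNPs whose marginal association with the exposure passes
    the genome-wide significance threshold; order preserved.

    Accepts either a :class:`SimulatedDataset` or an explicit (G, exposure)
    pair. An empty result is allowed; downstream fitting rejects it.
    """
    if isinstance(dataset_or_G, SimulatedDataset):
        G = dataset_or_G.genotypes
        x = dataset_or_G.exposure
        if exposure is not None:
            raise ValueError("pass either a dataset or (G, exposure), not both")
    else:
        G = np.asarray(dataset_or_G, dtype=float)
        if exposure is None:
            raise ValueError("exposure vector required when passing a matrix")
        x = np.asarray(exposure, dtype=float)
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    p = marginal_gwas_pvalues(G, x)
    return np.flatnonzero(p < p_threshold)


def _poly(*coefs: float) -> CausalFunction:
    return CausalFunction.polynomial(0.0, *coefs)


#: Named scenario presets: causal-function and confounding variations, all
#: other parameters at the base settings (n=100,000, m=100, h²=0.5,
#: q_x=0.2, q_y=0.5, q_y2=0).
SCENARIOS: dict[str, SimulationSettings] = {
    "base": SimulationSettings(),
    "null": SimulationSettings(causal_function=_poly(0.0)),
    "linear": SimulationSettings(causal_function=_poly(0.1)),
    "stronger": SimulationSettings(causal_function=_poly(0.3, 0.1)),
    "weak_quadratic": SimulationSettings(causal_function=_poly(0.1, 0.01)),
    "cubic": SimulationSettings(causal_function=_poly(0.1, 0.05, 0.05)),
    "fourth_order": SimulationSettings(causal_function=_poly(0.1, 0.05, 0.0, 0.05)),
    "third_fourth": SimulationSettings(causal_function=_poly(0.1, 0.05, 0.03, 0.01)),
    "exponential": SimulationSettings(
        causal_function=CausalFunction(family="exponential", scale=0.1)
    ),
    "signed_sqrt": SimulationSettings(
        causal_function=CausalFunction(family="signed_sqrt", scale=0.1)
    ),
    "sigmoid_1": SimulationSettings(
        causal_function=CausalFunction(family="sigmoid", scale=0.1, steepness=1.0)
    ),
    "sigmoid_2": SimulationSettings(
        causal_function=CausalFunction(family="sigmoid", scale=0.1, steepness=2.0)
    ),
    "sigmoid_3": SimulationSettings(
        causal_function=CausalFunction(family="sigmoid", scale=0.1, steepness=3.0)
    ),
    "strong_confounding": SimulationSettings(q_x=0.5, q_y=0.8),
    "negative_confounding": SimulationSettings(q_y=-0.5),
    "quadratic_confounding_01": SimulationSettings(q_y2=0.1),
    "quadratic_confounding_02": SimulationSettings(q_y2=0.2),
    "linear_quadratic_confounding": SimulationSettings(
        causal_function=_poly(0.1), q_y2=0.2
    ),
    "high_polygenicity": SimulationSettings(n_causal_snps=10_000, heritability=0.3),
}


def get_scenario(name: str, **overrides) -> SimulationSettings:
    """Look up a scenario preset by name, optionally overriding fields
    (e.g. ``get_scenario("base", n_samples=10_000, seed=7)``)."""
    try:
        base = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    return base.with_(**overrides) if overrides else base
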