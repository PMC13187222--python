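"""Two-group ordinal Likert simulation from a graded factor model.

Each item's latent response is a linear combination of correlated normal
factors plus independent normal residual noise, scaled to unit total
variance; six ordered thresholds cut the continuum into categories 1..7.
Group membership shifts the latent item mean only (scalar-invariant
generation), unless explicit non-invariance perturbations of loadings or
thresholds are supplied for the case group. This is exactly the
data-generating family assumed by polychoric correlations and
weighted-least-squares ordinal factor analysis, so every downstream stage
of the pipeline can be validated against known ground truth.

The observed-scale standardized group difference (Cohen's d) implied by a
latent mean shift is available in closed form by integrating the category
probabilities of the thresholded normal; :func:`induce_d_profile` inverts
that map to hit a target d per item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from scalenet.types import CASE, COMPARISON, ResponseMatrix

#: Default reverse-coded items of the 65-item instrument.
DEFAULT_REVERSE_ITEMS = frozenset({"IP6", "IP13", "IP21", "IP55"})

_CATS = np.arange(1, 8, dtype=float)


@dataclass
class Noninvariance:
    """Measurement perturbations applied to the case group only."""

    loading_delta: np.ndarray | None = None  # items x factors
    threshold_delta: np.ndarray | None = None  # items x 6

    def is_null(self) -> bool:
        return (self.loading_delta is None or not np.any(self.loading_delta)) and (
            self.threshold_delta is None or not np.any(self.threshold_delta)
        )


@dataclass
class SimulationConfig:
    """Parameters of the two-group graded factor model.

    Attributes
    ----------
    n_per_group : (n_case, n_comparison).
    loadings : items x factors matrix; squared row norm (through the factor
        correlation) must be <= 1 so the residual variance is non-negative.
    factor_correlation : factor x factor correlation matrix (positive definite).
    group_shift : per-item latent mean offset of the case group.
    thresholds : items x 6 strictly increasing cut points on the latent scale.
    reverse_items : items emitted on the reversed scale (8 - x).
    noninvariance : optional loading/threshold perturbations for the case group.
    """

    n_per_group: tuple[int, int]
    loadings: np.ndarray
    factor_correlation: np.ndarray
    group_shift: np.ndarray
    thresholds: np.ndarray
    item_ids: list[str] = field(default_factory=list)
    reverse_items: frozenset[str] = frozenset()
    noninvariance: Noninvariance | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.factor_correlation = np.atleast_2d(
            np.asarray(self.factor_correlation, dtype=float)
        )
        self.group_shift = np.asarray(self.group_shift, dtype=float)
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        p = self.loadings.shape[0]
        if not self.item_ids:
            self.item_ids = [f"IP{i + 1}" for i in range(p)]
        if self.thresholds.shape[0] == 1 and p > 1:
            self.thresholds = np.repeat(self.thresholds, p, axis=0)
        self.validate()

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def validate(self) -> None:
        if min(self.n_per_group) < 1:
            raise ValueError("group sizes must be positive")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            bad = np.where(np.any(np.diff(self.thresholds, axis=1) <= 0, axis=1))[0][0]
            raise ValueError(
                f"thresholds must be strictly increasing (item {self.item_ids[bad]})"
            )
        h2 = self.communalities()
        if np.any(h2 > 1.0 + 1e-12):
            bad = int(np.argmax(h2))
            raise ValueError(
                f"communality exceeds 1 for item {self.item_ids[bad]} "
                f"(h2 = {h2[bad]:.4f}); shrink the loadings"
            )
        if self.n_factors > 1:
            eig = np.linalg.eigvalsh(self.factor_correlation)
            if eig.min() <= 0:
                raise ValueError("factor correlation matrix must be positive definite")
        if self.group_shift.shape != (self.n_items,):
            raise ValueError("group_shift must have one entry per item")

    def communalities(self) -> np.ndarray:
        lam = self.loadings
        return np.einsum("if,fg,ig->i", lam, self.factor_correlation, lam)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_per_group": list(self.n_per_group),
                "loadings": self.loadings.tolist(),
                "factor_correlation": self.factor_correlation.tolist(),
                "group_shift": self.group_shift.tolist(),
                "thresholds": self.thresholds.tolist(),
                "item_ids": self.item_ids,
                "reverse_items": sorted(self.reverse_items),
                "seed": self.seed,
            },
            indent=2,
        )


def default_thresholds(n_items: int, spread: float = 2.5) -> np.ndarray:
    """Equally spaced thresholds symmetric about 0 on the unit-variance scale."""
    row = np.linspace(-spread, spread, 6)
    return np.repeat(row[None, :], n_items, axis=0)


def two_factor_config(
    n_per_group: tuple[int, int] = (196, 196),
    n_items: int = 65,
    loading: float = 0.7,
    factor_correlation: float = 0.58,
    seed: int = 0,
    reverse_items: frozenset[str] = DEFAULT_REVERSE_ITEMS,
) -> SimulationConfig:
    """Block-structured two-factor configuration: the first ~2/3 of items load
    on factor 1, the rest on factor 2, all with the same loading."""
    split = (2 * n_items) // 3
    lam = np.zeros((n_items, 2))
    lam[:split, 0] = loading
    lam[split:, 1] = loading
    phi = np.array([[1.0, factor_correlation], [factor_correlation, 1.0]])
    return SimulationConfig(
        n_per_group=n_per_group,
        loadings=lam,
        factor_correlation=phi,
        group_shift=np.zeros(n_items),
        thresholds=default_thresholds(n_items),
        reverse_items=frozenset(r for r in reverse_items if int(r[2:]) <= n_items),
        seed=seed,
    )


def _case_params(config: SimulationConfig):
    """Loadings and thresholds effective in the case group."""
    lam = config.loadings
    tau = config.thresholds
    ni = config.noninvariance
    if ni is not None:
        if ni.loading_delta is not None:
            lam = lam + np.asarray(ni.loading_delta, dtype=float)
        if ni.threshold_delta is not None:
            tau = tau + np.asarray(ni.threshold_delta, dtype=float)
    return lam, tau


def generate_responses(config: SimulationConfig) -> ResponseMatrix:
    """Draw a two-group response matrix from the graded factor model.

    Deterministic for a fixed seed. Case participants come first; their
    latent item means are offset by ``group_shift``. Reverse-coded items are
    emitted on the reversed raw scale (a high latent trait maps to a low
    rating).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_case, n_comp = config.n_per_group
    n = n_case + n_comp
    p, k = config.n_items, config.n_factors

    chol = np.linalg.cholesky(config.factor_correlation)
    factors = rng.standard_normal((n, k)) @ chol.T
    resid = rng.standard_normal((n, p))

    lam_case, tau_case = _case_params(config)
    resid_sd = np.sqrt(np.clip(1.0 - config.communalities(), 0.0, None))
    h2_case = np.einsum(
        "if,fg,ig->i", lam_case, config.factor_correlation, lam_case
    )
    resid_sd_case = np.sqrt(np.clip(1.0 - h2_case, 0.0, None))

    latent = np.empty((n, p))
    latent[:n_case] = (
        factors[:n_case] @ lam_case.T
        + resid[:n_case] * resid_sd_case
        + config.group_shift
    )
    latent[n_case:] = factors[n_case:] @ config.loadings.T + resid[n_case:] * resid_sd

    values = np.empty((n, p), dtype=int)
    values[:n_case] = 1 + (latent[:n_case, :, None] > tau_case[None]).sum(axis=2)
    values[n_case:] = 1 + (
        latent[n_case:, :, None] > config.thresholds[None]
    ).sum(axis=2)

    for j, item in enumerate(config.item_ids):
        if item in config.reverse_items:
            values[:, j] = 8 - values[:, j]

    group = np.array([CASE] * n_case + [COMPARISON] * n_comp, dtype=object)
    return ResponseMatrix(values=values, group=group, item_ids=list(config.item_ids))


def category_probabilities(
    thresholds_row: np.ndarray, mean: float = 0.0, sd: float = 1.0
) -> np.ndarray:
    """P(category = 1..7) for a thresholded N(mean, sd^2) latent response."""
    cdf = norm.cdf((np.asarray(thresholds_row) - mean) / sd)
    return np.diff(np.concatenate(([0.0], cdf, [1.0])))


def _moments(thresholds_row: np.ndarray, mean: float) -> tuple[float, float]:
    p = category_probabilities(thresholds_row, mean)
    m = float((_CATS * p).sum())
    v = float((_CATS**2 * p).sum() - m**2)
    return m, v


def implied_observed_d(thresholds_row: np.ndarray, shift: float) -> float:
    """Model-implied observed-scale pooled-SD d for a latent mean shift.

    Equal group sizes assumed; the latent response has unit variance in
    both groups.
    """
    m1, v1 = _moments(thresholds_row, shift)
    m0, v0 = _moments(thresholds_row, 0.0)
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0:
        raise ValueError("degenerate thresholds: zero category variance")
    return (m1 - m0) / pooled


def max_reachable_d(thresholds_row: np.ndarray) -> float:
    """Supremum of the observed d as the latent shift grows (saturation at 7)."""
    m0, v0 = _moments(thresholds_row, 0.0)
    return (7.0 - m0) / np.sqrt(v0 / 2.0)


def induce_d_profile(
    target_d: np.ndarray | dict[str, float], config: SimulationConfig
) -> SimulationConfig:
    """Return a config whose group_shift reproduces the target observed d.

    Solves, per item, implied_observed_d(thresholds, shift) = target to
    within 1e-3 by root bracketing. Raises a diagnostic error naming the
    item when the target exceeds what the thresholds allow (the item
    saturates at category 7 first).
    """
    if isinstance(target_d, dict):
        target = np.array([target_d[i] for i in config.item_ids], dtype=float)
    else:
        target = np.asarray(target_d, dtype=float)
    if target.shape != (config.n_items,):
        raise ValueError("target_d must have one value per item")
    if np.any(~np.isfinite(target)) or np.any(target < 0):
        raise ValueError("target_d must be finite and non-negative")

    shifts = np.zeros(config.n_items)
    for j in range(config.n_items):
        t = target[j]
        if t == 0.0:
            continue
        tau = config.thresholds[j]
        ceiling = max_reachable_d(tau)
        if t >= ceiling - 1e-6:
            raise ValueError(
                f"target d = {t:.3f} unreachable for item {config.item_ids[j]}: "
                f"the observed scale saturates at d = {ceiling:.3f}"
            )
        hi = 1.0
        while implied_observed_d(tau, hi) < t:
            hi *= 2.0
            if hi > 1e4:  # pragma: no cover - guarded by the ceiling check
                raise ValueError(f"cannot bracket shift for item {config.item_ids[j]}")
        shifts[j] = optimize.brentq(
            lambda s: implied_observed_d(tau, s) - t, 0.0, hi, xtol=1e-8
        )

    out = SimulationConfig(
        n_per_group=config.n_per_group,
        loadings=config.loadings.copy(),
        factor_correlation=config.factor_correlation.copy(),
        group_shift=shifts,
        thresholds=config.thresholds.copy(),
        item_ids=list(config.item_ids),
        reverse_items=config.reverse_items,
        noninvariance=config.noninvariance,
        seed=config.seed,
    )
    return out
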