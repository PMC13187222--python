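"""Ordinal confirmatory factor analysis and cross-group measurement invariance.

Polychoric correlations are estimated by the classic two-step method:
thresholds from the marginal category proportions via the normal quantile,
then the correlation of the underlying bivariate normal by maximizing the
contingency-table likelihood. Models are fit by diagonally weighted least
squares (DWLS): the weighted squared distance between the sample polychoric
correlation vector and the model-implied one is minimized, with weights
given by the (estimated) asymptotic variances of the polychoric
correlations. The chi-square statistic is (n-1) times the minimized
discrepancy, without the mean-and-variance robust adjustment of full
WLSMV; fit indices derived from it (CFI, TLI, RMSEA, SRMR) are flagged as
such in reports.

Measurement invariance across two groups is tested sequentially:

* configural - same factor pattern, all parameters free per group
  (each group's latent responses standardized);
* metric - factor loadings equal across groups on a common unstandardized
  scale; the second group's factor variances and covariance are freed,
  residual variances held at their group-1 values so the loading
  constraint is identified from correlation structure alone;
* scalar - additionally the ordinal thresholds are constrained equal
  (thresholds are the ordinal analog of intercepts), with the second
  group's factor means freed. Shared thresholds are profiled out of the
  weighted-least-squares objective in closed form.

Decisions follow the conventional change-in-fit rules: a level passes when
the CFI drop from the previous level is at most 0.01 (the RMSEA increase,
threshold 0.015, is reported alongside); chi-square difference tests are
also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps
from scipy.stats import norm

from scalenet._bvn import cell_probabilities
from scalenet.types import CASE, ResponseMatrix

_RHO_BOUND = 0.999
_W_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# polychoric correlations


def _thresholds_from_margin(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normal-quantile thresholds of an ordinal vector and the category codes."""
    uniq, codes = np.unique(x, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("variable has fewer than 2 observed categories")
    counts = np.bincount(codes)
    cum = np.cumsum(counts)[:-1] / x.size
    return norm.ppf(cum), codes


def _pair_loglik(table: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray):
    nz = table > 0
    counts = table[nz]

    def ll(rho: float) -> float:
        p = cell_probabilities(tau_x, tau_y, rho)
        return float((counts * np.log(np.maximum(p[nz], 1e-300))).sum())

    return ll


def _polychoric_var(
    table: np.ndarray, tau_x: np.ndarray, tau_y: np.ndarray, rho: float
) -> float:
    """Asymptotic variance of the two-step polychoric estimate.

    Influence-function (sandwich) form that propagates the sampling noise of
    the margin-based thresholds into rho-hat, as in the standard ordinal-SEM
    weight matrices. Derivatives are taken by finite differences of the
    cell log-probabilities.
    """
    n = table.sum()
    phat = table / n
    h = 1e-5

    def ln_p(tx, ty, r):
        return np.log(np.maximum(cell_probabilities(tx, ty, r), 1e-300))

    def score(tx, ty):
        return (ln_p(tx, ty, rho + h) - ln_p(tx, ty, rho - h)) / (2 * h)

    s = score(tau_x, tau_y)
    info = float((phat * s**2).sum())
    if info <= 0:
        return 1.0 / n

    # cross-derivatives of the score wrt each threshold
    def h_terms(tau, axis):
        out = np.empty(tau.size)
        for k in range(tau.size):
            t2 = tau.copy()
            t2[k] += h
            s2 = score(t2, tau_y) if axis == 0 else score(tau_x, t2)
            out[k] = float((phat * (s2 - s)).sum()) / h
        return out

    hx = h_terms(tau_x, 0)
    hy = h_terms(tau_y, 1)
    # influence of the margin-based thresholds: (1[cat <= k] - c_k) / pdf(tau_k)
    cx = norm.cdf(tau_x)
    cy = norm.cdf(tau_y)
    a_idx = np.arange(table.shape[0])
    b_idx = np.arange(table.shape[1])
    tx_inf = ((a_idx[:, None] <= np.arange(tau_x.size)[None, :]) - cx) / norm.pdf(tau_x)
    ty_inf = ((b_idx[:, None] <= np.arange(tau_y.size)[None, :]) - cy) / norm.pdf(tau_y)
    infl = (s + (tx_inf @ hx)[:, None] + (ty_inf @ hy)[None, :]) / info
    return float((phat * infl**2).sum() / n)


def _polychoric_pair(
    codes_x: np.ndarray,
    codes_y: np.ndarray,
    tau_x: np.ndarray,
    tau_y: np.ndarray,
) -> tuple[float, float]:
    """Two-step polychoric rho and its asymptotic variance estimate."""
    kx, ky = tau_x.size + 1, tau_y.size + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (codes_x, codes_y), 1.0)
    ll = _pair_loglik(table, tau_x, tau_y)
    res = optimize.minimize_scalar(
        lambda r: -ll(r),
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    if abs(rho) > _RHO_BOUND - 1e-4:
        warnings.warn(
            "polychoric estimate at the boundary; clipped to +-0.999", stacklevel=3
        )
        rho = float(np.sign(rho) * _RHO_BOUND)
    var = _polychoric_var(table, tau_x, tau_y, rho)
    return rho, float(max(var, _W_FLOOR))


def polychoric(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Polychoric correlation of two ordinal vectors.

    Returns (rho, thresholds_x, thresholds_y). Invariant to relabeling the
    categories by any strictly increasing map, since only the ordered
    contingency table enters.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    tau_x, cx = _thresholds_from_margin(x)
    tau_y, cy = _thresholds_from_margin(y)
    rho, _ = _polychoric_pair(cx, cy, tau_x, tau_y)
    return rho, tau_x, tau_y


def polychoric_matrix(
    data: np.ndarray | ResponseMatrix,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Pairwise polychoric correlation matrix with asymptotic-variance weights.

    Returns (R, per-item thresholds, per-pair variance matrix).
    """
    if isinstance(data, ResponseMatrix):
        data = data.values
    data = np.asarray(data)
    n, p = data.shape
    taus, codes = [], []
    for j in range(p):
        t, c = _thresholds_from_margin(data[:, j])
        taus.append(t)
        codes.append(c)
    r = np.eye(p)
    var = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rho, v = _polychoric_pair(codes[i], codes[j], taus[i], taus[j])
            r[i, j] = r[j, i] = rho
            var[i, j] = var[j, i] = v
    return r, taus, var


# ---------------------------------------------------------------------------
# model specification


@dataclass
class CfaSpec:
    """Confirmatory model: item-to-factor map plus optional error covariances."""

    factor_map: dict[str, list[str]]
    error_covariances: list[tuple[str, str]] = field(default_factory=list)
    estimator: str = "dwls"
    identification: str = "variance_std"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for items in self.factor_map.values():
            for it in items:
                if it in seen:
                    raise ValueError(f"item {it!r} appears in more than one factor")
                seen.add(it)
        for a, b in self.error_covariances:
            if a == b:
                raise ValueError("error covariance must link two distinct items")
            if a not in seen or b not in seen:
                raise ValueError(f"error covariance on unknown item: {a}, {b}")
        if self.estimator not in {"dwls", "uls"}:
            raise ValueError("estimator must be 'dwls' or 'uls'")

    @property
    def items(self) -> list[str]:
        return [it for items in self.factor_map.values() for it in items]

    @property
    def factor_names(self) -> list[str]:
        return list(self.factor_map)

    def to_json_dict(self) -> dict:
        return {
            "factor_map": self.factor_map,
            "error_covariances": [list(p) for p in self.error_covariances],
            "estimator": self.estimator,
            "identification": self.identification,
        }


class _Structure:
    """Precomputed index arrays for fast implied-correlation evaluation."""

    def __init__(self, spec: CfaSpec):
        self.items = spec.items
        self.p = len(self.items)
        self.k = len(spec.factor_map)
        pos = {it: i for i, it in enumerate(self.items)}
        self.f_idx = np.empty(self.p, dtype=int)
        for f, (name, members) in enumerate(spec.factor_map.items()):
            for it in members:
                self.f_idx[pos[it]] = f
        self.pi, self.pj = np.triu_indices(self.p, k=1)
        self.fa = self.f_idx[self.pi]
        self.fb = self.f_idx[self.pj]
        self.n_pairs = self.pi.size
        # positions of the error-covariance pairs within the pair vector
        pair_pos = {(int(a), int(b)): t for t, (a, b) in enumerate(zip(self.pi, self.pj))}
        self.ec_pos = np.array(
            [
                pair_pos[tuple(sorted((pos[a], pos[b])))]
                for a, b in spec.error_covariances
            ],
            dtype=int,
        )
        self.n_ec = self.ec_pos.size
        self.n_phi = self.k * (self.k - 1) // 2
        self.phi_iu = np.triu_indices(self.k, k=1)

    def phi_matrix(self, phi_off: np.ndarray, diag: np.ndarray | None = None) -> np.ndarray:
        phi = np.eye(self.k) if diag is None else np.diag(diag)
        phi[self.phi_iu] = phi_off if diag is None else phi_off * np.sqrt(
            diag[self.phi_iu[0]] * diag[self.phi_iu[1]]
        )
        phi[(self.phi_iu[1], self.phi_iu[0])] = phi[self.phi_iu]
        return phi

    def implied_offdiag(
        self, lam: np.ndarray, phi: np.ndarray, psi: np.ndarray
    ) -> np.ndarray:
        r = lam[self.pi] * lam[self.pj] * phi[self.fa, self.fb]
        if self.n_ec:
            r = r.copy()
            r[self.ec_pos] += psi
        return r


# ---------------------------------------------------------------------------
# single-group fit


@dataclass
class CfaFit:
    item_ids: list[str]
    factor_names: list[str]
    loadings: np.ndarray  # items x factors (zeros off-pattern)
    phi: np.ndarray
    error_variances: np.ndarray
    error_covariances: dict[tuple[str, str], float]
    thresholds: dict[str, np.ndarray]
    fit: dict
    omega: dict[str, float]
    converged: bool
    n_obs: int
    note: str = "DWLS on polychoric correlations; unadjusted (non-robust) test statistic"

    def loading_vector(self) -> np.ndarray:
        return self.loadings.sum(axis=1)


def _fit_indices(
    f_min: float,
    chi2: float,
    df: int,
    chi2_b: float,
    df_b: int,
    n: int,
    srmr: float,
) -> dict:
    excess = max(chi2 - df, 0.0)
    excess_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 - excess / max(excess_b, excess, np.finfo(float).tiny)
    if df > 0 and chi2_b / max(df_b, 1) > 1.0:
        tli = (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0)
    else:
        tli = 1.0
    rmsea = np.sqrt(excess / (df * max(n - 1, 1))) if df > 0 else 0.0
    return {
        "discrepancy": float(f_min),
        "chi_square": float(chi2),
        "df": int(df),
        "cfi": float(min(cfi, 1.0)),
        "tli": float(min(tli, 1.0)),
        "rmsea": float(rmsea),
        "srmr": float(srmr),
    }


def _minimize(obj, x0, bounds, restarts: int = 3, seed: int = 0):
    rng = np.random.default_rng(seed)
    best = None
    for t in range(restarts):
        start = x0 if t == 0 else np.clip(
            x0 + rng.normal(0, 0.1, size=x0.size),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        res = optimize.minimize(
            obj,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def _omega(
    struct: _Structure,
    lam: np.ndarray,
    theta: np.ndarray,
    psi: np.ndarray,
    factor_names: list[str],
    spec: CfaSpec,
) -> dict[str, float]:
    """McDonald's omega per factor: (sum lambda)^2 over itself + residual mass."""
    pos = {it: i for i, it in enumerate(struct.items)}
    out = {}
    for f, name in enumerate(factor_names):
        members = np.flatnonzero(struct.f_idx == f)
        s_lam = lam[members].sum()
        s_theta = theta[members].sum()
        s_psi = 0.0
        for t, (a, b) in enumerate(spec.error_covariances):
            if struct.f_idx[pos[a]] == f and struct.f_idx[pos[b]] == f:
                s_psi += psi[t]
        out[name] = float(s_lam**2 / (s_lam**2 + s_theta + 2.0 * s_psi))
    return out


def fit_cfa(
    matrix: ResponseMatrix | np.ndarray | None,
    spec: CfaSpec,
    corr: np.ndarray | None = None,
    n_obs: int | None = None,
    seed: int = 0,
) -> CfaFit:
    """Fit a single-group ordinal CFA by DWLS on polychoric correlations.

    Pass raw ordinal data (ResponseMatrix or array; columns matched to the
    spec's items) or a precomputed correlation matrix via ``corr`` together
    with ``n_obs`` (unit weights are then used). Factor variances are fixed
    to 1, so loadings are standardized.
    """
    struct = _Structure(spec)
    thresholds: dict[str, np.ndarray] = {}
    if corr is not None:
        if n_obs is None:
            raise ValueError("n_obs is required with a precomputed correlation matrix")
        r = np.asarray(corr, dtype=float)
        w = np.ones((struct.p, struct.p))
    else:
        if isinstance(matrix, ResponseMatrix):
            matrix = matrix.subset(spec.items)
            data = matrix.values
        else:
            data = np.asarray(matrix)
            if data.shape[1] != struct.p:
                raise ValueError("data columns do not match spec items")
        n_obs = data.shape[0]
        r, taus, w = polychoric_matrix(data)
        if spec.estimator == "uls":
            w = np.ones_like(w)
        thresholds = {it: taus[j] for j, it in enumerate(struct.items)}
    n_free = struct.p + struct.n_phi + struct.n_ec
    if n_obs <= n_free:
        raise ValueError("model has more free parameters than observations")

    s = r[struct.pi, struct.pj]
    if corr is not None:
        wv = np.ones(s.size)
    else:
        # rescale Var(rho_hat) to the asymptotic variance of sqrt(n) * rho_hat,
        # so the DWLS chi-square is (n-1) times the minimized discrepancy
        wv = np.maximum(w[struct.pi, struct.pj], _W_FLOOR) * (n_obs - 1)

    def unpack(x):
        lam = x[: struct.p]
        phi_off = x[struct.p : struct.p + struct.n_phi]
        psi = x[struct.p + struct.n_phi :]
        return lam, phi_off, psi

    def objective(x):
        lam, phi_off, psi = unpack(x)
        phi = struct.phi_matrix(phi_off)
        res = s - struct.implied_offdiag(lam, phi, psi)
        return float((res**2 / wv).sum())

    x0 = np.concatenate(
        [np.full(struct.p, 0.6), np.full(struct.n_phi, 0.5), np.zeros(struct.n_ec)]
    )
    bounds = (
        [(-0.995, 0.995)] * struct.p
        + [(-0.99, 0.99)] * struct.n_phi
        + [(-0.8, 0.8)] * struct.n_ec
    )
    best = _minimize(objective, x0, bounds, seed=seed)
    if not best.success and best.fun > 1e-6:
        grad_norm = float(np.abs(best.jac).max()) if best.jac is not None else np.nan
        raise RuntimeError(
            f"CFA did not converge (status {best.status}, max|grad| = {grad_norm:.3g})"
        )
    lam, phi_off, psi = unpack(best.x)
    phi = struct.phi_matrix(phi_off)
    theta = 1.0 - lam**2

    f_min = best.fun
    chi2 = (n_obs - 1) * f_min
    df = struct.n_pairs - n_free
    f_base = float((s**2 / wv).sum())
    chi2_b = (n_obs - 1) * f_base
    resid = s - struct.implied_offdiag(lam, phi, psi)
    srmr = float(np.sqrt((resid**2).sum() * 2.0 / (struct.p * (struct.p + 1))))
    fit = _fit_indices(f_min, chi2, df, chi2_b, struct.n_pairs, n_obs, srmr)

    loadings = np.zeros((struct.p, struct.k))
    loadings[np.arange(struct.p), struct.f_idx] = lam
    return CfaFit(
        item_ids=struct.items,
        factor_names=spec.factor_names,
        loadings=loadings,
        phi=phi,
        error_variances=theta,
        error_covariances={
            tuple(pair): float(v) for pair, v in zip(spec.error_covariances, psi)
        },
        thresholds=thresholds,
        fit=fit,
        omega=_omega(struct, lam, theta, psi, spec.factor_names, spec),
        converged=bool(best.success or best.fun <= 1e-6),
        n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# measurement invariance


@dataclass
class InvarianceReport:
    levels: dict[str, dict]
    deltas: dict[str, dict]
    chi_square_diffs: dict[str, dict]
    decisions: dict[str, bool]
    thresholds_rule: dict
    converged: bool
    note: str = (
        "configural/metric/scalar on polychoric correlations (DWLS, unadjusted "
        "chi-square); scalar level constrains ordinal thresholds with group-2 "
        "factor means freed; residual variances held invariant from the metric "
        "level for identification"
    )


def _group_moments(data: np.ndarray):
    """Polychoric correlations, weights, and threshold moments for one group."""
    n, p = data.shape
    r, taus, var = polychoric_matrix(data)
    # thresholds on the fixed category grid 1..7 so groups align
    tau_hat = np.full((p, 6), np.nan)
    tau_w = np.full((p, 6), np.nan)
    for j in range(p):
        counts = np.bincount(data[:, j].astype(int), minlength=8)[1:8]
        cum = np.cumsum(counts)[:-1] / n
        ok = (cum > 0) & (cum < 1)
        t = norm.ppf(cum[ok])
        tau_hat[j, ok] = t
        tau_w[j, ok] = np.maximum(
            cum[ok] * (1 - cum[ok]) / (n * norm.pdf(t) ** 2), _W_FLOOR
        )
    return r, var, tau_hat, tau_w


def invariance_sequence(
    matrix: ResponseMatrix,
    spec: CfaSpec,
    thresholds: dict | None = None,
    case_label: str = CASE,
    seed: int = 0,
) -> InvarianceReport:
    """Configural / metric / scalar invariance testing across the two groups.

    ``thresholds`` configures the decision rule, keys ``delta_cfi_max``
    (default 0.01) and ``delta_rmsea_max`` (default 0.015). A level's
    pass/fail decision uses the CFI drop; the RMSEA change is reported.
    """
    rule = {"delta_cfi_max": 0.01, "delta_rmsea_max": 0.015}
    if thresholds:
        rule.update(thresholds)
    struct = _Structure(spec)
    sub = matrix.subset(spec.items)
    mask = sub.group_mask(case_label)
    groups = [sub.values[mask], sub.values[~mask]]
    ns = [g.shape[0] for g in groups]
    if min(ns) < 50:
        raise ValueError("invariance testing needs at least 50 participants per group")

    moments = [_group_moments(g) for g in groups]
    s_list = [m[0][struct.pi, struct.pj] for m in moments]
    # weights are the estimated Var of each moment (which carries the 1/n_g),
    # so every sum of residual^2 / Var below is directly on the chi-square scale
    w_list = [np.maximum(m[1][struct.pi, struct.pj], _W_FLOOR) for m in moments]
    valid = ~np.isnan(moments[0][2]) & ~np.isnan(moments[1][2])
    tau_hats = [np.where(valid, m[2], 0.0) for m in moments]
    tau_ws = [np.where(valid, m[3], 1.0) for m in moments]
    n_thr = int(valid.sum())
    n_total = sum(ns)
    total_moments = 2 * (struct.n_pairs + n_thr)

    chi2_b = sum(float((s**2 / w).sum()) for s, w in zip(s_list, w_list))
    df_b = 2 * struct.n_pairs

    levels: dict[str, dict] = {}
    converged_all = True

    # ---- configural: independent standardized fits per group
    config_chi2 = 0.0
    config_params = []
    for g in range(2):
        s, w = s_list[g], w_list[g]

        def obj(x, s=s, w=w):
            lam = x[: struct.p]
            phi = struct.phi_matrix(x[struct.p : struct.p + struct.n_phi])
            psi = x[struct.p + struct.n_phi :]
            res = s - struct.implied_offdiag(lam, phi, psi)
            return float((res**2 / w).sum())

        x0 = np.concatenate(
            [np.full(struct.p, 0.6), np.full(struct.n_phi, 0.5), np.zeros(struct.n_ec)]
        )
        bounds = (
            [(-0.995, 0.995)] * struct.p
            + [(-0.99, 0.99)] * struct.n_phi
            + [(-0.8, 0.8)] * struct.n_ec
        )
        res = _minimize(obj, x0, bounds, restarts=2, seed=seed + g)
        converged_all &= bool(res.success or res.fun < 1e-6)
        config_chi2 += res.fun
        config_params.append(res.x)
    df_c = total_moments - (2 * (struct.p + struct.n_phi + struct.n_ec) + 2 * n_thr)
    levels["configural"] = _mg_fit_entry(
        config_chi2, df_c, chi2_b, df_b, n_total, config_params
    )

    # ---- metric: shared (standardized) loadings; factor variances stay
    # fixed at 1 in both groups per the variance-standardized identification,
    # so the level tests equality of standardized loadings
    n_free_metric = struct.p + 2 * struct.n_phi + 2 * struct.n_ec

    def metric_implied(x):
        lam = x[: struct.p]
        i = struct.p
        phi1 = struct.phi_matrix(x[i : i + struct.n_phi])
        i += struct.n_phi
        phi2 = struct.phi_matrix(x[i : i + struct.n_phi])
        i += struct.n_phi
        psi1 = x[i : i + struct.n_ec]
        i += struct.n_ec
        psi2 = x[i : i + struct.n_ec]
        r1 = struct.implied_offdiag(lam, phi1, psi1)
        r2 = struct.implied_offdiag(lam, phi2, psi2)
        return r1, r2, lam

    def metric_obj(x):
        r1, r2, _ = metric_implied(x)
        return float(
            ((s_list[0] - r1) ** 2 / w_list[0]).sum()
            + ((s_list[1] - r2) ** 2 / w_list[1]).sum()
        )

    lam0 = (config_params[0][: struct.p] + config_params[1][: struct.p]) / 2.0
    x0_m = np.concatenate(
        [
            lam0,
            config_params[0][struct.p : struct.p + struct.n_phi],
            config_params[1][struct.p : struct.p + struct.n_phi],
            config_params[0][struct.p + struct.n_phi :],
            config_params[1][struct.p + struct.n_phi :],
        ]
    )
    bounds_m = (
        [(-0.995, 0.995)] * struct.p
        + [(-0.99, 0.99)] * (2 * struct.n_phi)
        + [(-0.8, 0.8)] * (2 * struct.n_ec)
    )
    res_m = _minimize(metric_obj, x0_m, bounds_m, restarts=2, seed=seed + 10)
    converged_all &= bool(res_m.success or res_m.fun < 1e-6)
    metric_chi2 = res_m.fun
    df_m = total_moments - (n_free_metric + 2 * n_thr)
    levels["metric"] = _mg_fit_entry(
        metric_chi2, df_m, chi2_b, df_b, n_total, [res_m.x]
    )

    # ---- scalar: shared thresholds (profiled out in closed form), group-2
    # factor means free; unit latent-response variances in both groups
    n_free_scalar = n_free_metric + struct.k + n_thr

    def scalar_obj(x):
        r1, r2, lam = metric_implied(x[: x.size - struct.k])
        kappa = x[-struct.k :]
        f_corr = ((s_list[0] - r1) ** 2 / w_list[0]).sum() + (
            (s_list[1] - r2) ** 2 / w_list[1]
        ).sum()
        # group-2 latent item means m_i = lambda_i * kappa_f; the shared
        # threshold solving the two-group weighted least squares is closed form
        m = (lam * kappa[struct.f_idx])[:, None]
        a, b = tau_hats[0], tau_hats[1]
        w1, w2 = tau_ws[0], tau_ws[1]
        tau = (a / w1 + (b + m) / w2) / (1.0 / w1 + 1.0 / w2)
        f_thr = (a - tau) ** 2 / w1 + (b - (tau - m)) ** 2 / w2
        return float(f_corr) + float(f_thr[valid].sum())

    x0_s = np.concatenate([res_m.x, np.zeros(struct.k)])
    bounds_s = bounds_m + [(-4.0, 4.0)] * struct.k
    res_s = _minimize(scalar_obj, x0_s, bounds_s, restarts=2, seed=seed + 20)
    converged_all &= bool(res_s.success or res_s.fun < 1e-6)
    scalar_chi2 = res_s.fun
    df_s = total_moments - n_free_scalar
    levels["scalar"] = _mg_fit_entry(
        scalar_chi2, df_s, chi2_b, df_b, n_total, [res_s.x]
    )

    # ---- deltas and decisions
    order = ["configural", "metric", "scalar"]
    deltas: dict[str, dict] = {}
    diffs: dict[str, dict] = {}
    decisions: dict[str, bool] = {"configural": levels["configural"]["cfi"] >= 0.90}
    for prev, cur in zip(order[:-1], order[1:]):
        d_cfi = levels[cur]["cfi"] - levels[prev]["cfi"]
        d_rmsea = levels[cur]["rmsea"] - levels[prev]["rmsea"]
        deltas[cur] = {"delta_cfi": d_cfi, "delta_rmsea": d_rmsea}
        d_chi = max(levels[cur]["chi_square"] - levels[prev]["chi_square"], 0.0)
        d_df = levels[cur]["df"] - levels[prev]["df"]
        diffs[cur] = {
            "delta_chi_square": d_chi,
            "delta_df": d_df,
            "p": float(sps.chi2.sf(d_chi, d_df)) if d_df > 0 else np.nan,
        }
        decisions[cur] = bool(-d_cfi <= rule["delta_cfi_max"])
    return InvarianceReport(
        levels=levels,
        deltas=deltas,
        chi_square_diffs=diffs,
        decisions=decisions,
        thresholds_rule=rule,
        converged=converged_all,
    )


def _mg_fit_entry(chi2, df, chi2_b, df_b, n, params) -> dict:
    excess = max(chi2 - df, 0.0)
    excess_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 - excess / max(excess_b, excess, np.finfo(float).tiny)
    tli = (
        (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0)
        if df > 0 and chi2_b > df_b
        else 1.0
    )
    rmsea = np.sqrt(excess / (df * max(n - 1, 1))) if df > 0 else 0.0
    return {
        "chi_square": float(chi2),
        "df": int(df),
        "cfi": float(min(cfi, 1.0)),
        "tli": float(min(tli, 1.0)),
        "rmsea": float(rmsea),
        "params": [np.asarray(p).tolist() for p in params],
    }
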