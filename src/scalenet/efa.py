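"""Exploratory factor analysis for Likert-type item data.

Provides the classic EFA toolchain: factorability diagnostics (KMO,
Bartlett's sphericity test), factor-count selection by parallel analysis
with principal-axis eigenvalues, principal axis factoring (PAF) by
iterated eigendecomposition of the reduced correlation matrix, direct
oblimin rotation by gradient projection, maximum-likelihood-discrepancy
fit indices (TLI, RMSEA with 90% CI), and Thurstone regression factor
scores with their reliability.

Correlations are Pearson on the raw 1-7 ratings by default; pass a
precomputed (e.g. polychoric) matrix where ordinal correlations are wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from scalenet.types import ResponseMatrix


@dataclass
class FactorSolution:
    """Oblique (or single-factor) EFA solution with fit and score reliability."""

    loadings: np.ndarray  # item x factor pattern matrix
    phi: np.ndarray  # factor correlation matrix
    communalities: np.ndarray
    variance_explained: np.ndarray  # per-factor proportion of total variance
    total_variance_explained: float
    fit: dict = field(default_factory=dict)
    score_reliability: dict = field(default_factory=dict)
    item_ids: list[str] = field(default_factory=list)
    heywood: bool = False


@dataclass
class ParallelResult:
    observed_eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray
    n_factors: int


def _as_data(matrix) -> np.ndarray:
    if isinstance(matrix, ResponseMatrix):
        return matrix.values.astype(float)
    return np.asarray(matrix, dtype=float)


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    return corr


def kmo(corr: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy, overall and per item.

    Contrasts squared correlations with squared anti-image partial
    correlations. The degenerate identity-matrix case (no correlations at
    all) is defined as KMO = 0.
    """
    corr = _check_corr(corr)
    p = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            "correlation matrix is singular; add a ridge or drop collinear items"
        ) from None
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(p, dtype=bool)
    r2 = corr[off] ** 2
    q2 = partial[off] ** 2
    denom = r2.sum() + q2.sum()
    overall = 0.0 if denom == 0 else r2.sum() / denom
    per_item = np.zeros(p)
    for i in range(p):
        mask = np.ones(p, dtype=bool)
        mask[i] = False
        ri = (corr[i, mask] ** 2).sum()
        qi = (partial[i, mask] ** 2).sum()
        per_item[i] = 0.0 if ri + qi == 0 else ri / (ri + qi)
    return float(overall), per_item


def bartlett_sphericity(corr: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is an identity."""
    corr = _check_corr(corr)
    p = corr.shape[0]
    if n <= p:
        raise ValueError("Bartlett's test needs more observations than items")
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(sps.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations of each item on all others."""
    inv = np.linalg.inv(corr)
    return 1.0 - 1.0 / np.diag(inv)


def _reduced_eigenvalues(corr: np.ndarray) -> np.ndarray:
    red = corr.copy()
    np.fill_diagonal(red, smc(corr))
    return np.linalg.eigvalsh(red)[::-1]


def parallel_analysis(
    matrix,
    n_resamples: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> ParallelResult:
    """Factor count by comparing principal-axis eigenvalues with resampled noise.

    Observed eigenvalues come from the reduced correlation matrix (SMC on
    the diagonal, as in PAF). The reference curve is the per-position
    ``quantile`` of the same eigenvalues computed on data with each column
    independently permuted, which preserves the marginal category
    distributions while destroying inter-item structure. The retained count
    is the length of the leading run where observed > reference.
    """
    data = _as_data(matrix)
    n, p = data.shape
    if n <= p:
        raise ValueError("parallel analysis needs more participants than items")
    if n_resamples < 100:
        raise ValueError("n_resamples must be at least 100")
    corr = np.corrcoef(data, rowvar=False)
    observed = _reduced_eigenvalues(corr)

    rng = np.random.default_rng(seed)
    ref = np.empty((n_resamples, p))
    shuffled = data.copy()
    for b in range(n_resamples):
        for j in range(p):
            rng.shuffle(shuffled[:, j])
        ref[b] = _reduced_eigenvalues(np.corrcoef(shuffled, rowvar=False))
    reference = np.quantile(ref, quantile, axis=0)

    k = 0
    while k < p and observed[k] > reference[k]:
        k += 1
    return ParallelResult(
        observed_eigenvalues=observed, reference_eigenvalues=reference, n_factors=k
    )


def paf(
    corr: np.ndarray,
    n_factors: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Principal axis factoring by iterated reduced eigendecomposition.

    Communalities start at the squared multiple correlations and are
    iterated until max |change| < tol. Returns (unrotated loadings,
    communalities, heywood_flag); a Heywood case (communality > 1) is
    clipped at 1 with a warning.

    Raises
    ------
    RuntimeError if the iteration does not converge within ``max_iter``.
    """
    corr = _check_corr(corr)
    p = corr.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must be in [1, n_items)")
    h2 = smc(corr)
    heywood = False
    red = corr.copy()
    for _ in range(max_iter):
        np.fill_diagonal(red, h2)
        vals, vecs = np.linalg.eigh(red)
        idx = np.argsort(vals)[::-1][:n_factors]
        lam = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
        new_h2 = (lam**2).sum(axis=1)
        if np.any(new_h2 > 1.0):
            heywood = True
            new_h2 = np.minimum(new_h2, 1.0)
        delta = np.abs(new_h2 - h2).max()
        h2 = new_h2
        if delta < tol:
            break
    else:
        raise RuntimeError(f"PAF did not converge in {max_iter} iterations")
    if heywood:
        warnings.warn("Heywood case in PAF: communality clipped at 1", stacklevel=2)
    # sign convention: majority-positive columns
    signs = np.where(lam.sum(axis=0) < 0, -1.0, 1.0)
    return lam * signs, h2, heywood


def _oblimin_criterion(lam: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Direct oblimin criterion value and gradient wrt the rotated loadings."""
    p, k = lam.shape
    l2 = lam**2
    n_mat = np.ones((k, k)) - np.eye(k)
    x = l2 @ n_mat
    if gamma != 0.0:
        x = (np.eye(p) - (gamma / p) * np.ones((p, p))) @ x
    f = float((l2 * x).sum()) / 4.0
    grad = lam * x
    return f, grad


def _gpa_oblique(
    loadings: np.ndarray,
    gamma: float,
    t0: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Gradient projection algorithm for oblique rotation (Jennrich 2002)."""
    a = loadings
    t = t0.copy()
    al = 1.0
    lam = a @ np.linalg.inv(t).T
    f, gq = _oblimin_criterion(lam, gamma)
    grad = -(lam.T @ gq @ np.linalg.inv(t)).T
    converged = False
    for _ in range(max_iter):
        gp = grad - t * (t * grad).sum(axis=0)
        s = np.sqrt((gp**2).sum())
        if s < tol:
            converged = True
            break
        al *= 2.0
        improved = False
        for _ in range(30):
            x = t - al * gp
            x /= np.sqrt((x**2).sum(axis=0))
            lam_t = a @ np.linalg.inv(x).T
            f_t, gq_t = _oblimin_criterion(lam_t, gamma)
            if f_t < f - 0.5 * s**2 * al:
                improved = True
                break
            al /= 2.0
        if not improved:
            # no step along the projected gradient improves the criterion:
            # treat as a (numerical) stationary point
            converged = True
            break
        t = x
        lam, f, gq = lam_t, f_t, gq_t
        grad = -(lam.T @ gq @ np.linalg.inv(t)).T
    phi = t.T @ t
    return lam, phi, f, converged


def oblimin_rotate(
    loadings: np.ndarray,
    gamma: float = 0.0,
    n_starts: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct oblimin (quartimin at gamma = 0) rotation of an EFA solution.

    Runs gradient projection from the identity plus random oblique starts
    and keeps the lowest criterion value. The model-implied matrix
    lambda phi lambda' is preserved exactly by construction. Factors are
    reordered by explained variance and sign-aligned.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim != 2 or loadings.shape[1] < 2:
        raise ValueError("rotation needs at least 2 factors")
    k = loadings.shape[1]
    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    starts = [np.eye(k)] + [
        np.linalg.qr(rng.standard_normal((k, k)))[0] for _ in range(n_starts - 1)
    ]
    for t0 in starts:
        lam, phi, f, ok = _gpa_oblique(loadings, gamma, t0)
        any_converged = any_converged or ok
        if best is None or f < best[2]:
            best = (lam, phi, f)
    if not any_converged:
        raise RuntimeError(
            f"oblimin rotation failed to converge; best criterion {best[2]:.6g}"
        )
    lam, phi, _ = best
    # sign-align (majority positive) and order by SS loadings
    signs = np.where(lam.sum(axis=0) < 0, -1.0, 1.0)
    lam = lam * signs
    phi = phi * np.outer(signs, signs)
    order = np.argsort(-(lam**2).sum(axis=0))
    return lam[:, order], phi[np.ix_(order, order)]


def ml_discrepancy(sample_corr: np.ndarray, implied: np.ndarray) -> float:
    """ML fit function: ln|Sigma| - ln|S| + tr(S Sigma^-1) - p."""
    p = sample_corr.shape[0]
    sign_i, logdet_i = np.linalg.slogdet(implied)
    sign_s, logdet_s = np.linalg.slogdet(sample_corr)
    if sign_i <= 0 or sign_s <= 0:
        raise ValueError("matrices must be positive definite")
    return float(
        logdet_i - logdet_s + np.trace(sample_corr @ np.linalg.inv(implied)) - p
    )


def efa_chi_square(
    sample_corr: np.ndarray,
    loadings: np.ndarray,
    phi: np.ndarray,
    n: int,
) -> tuple[float, int, float, int]:
    """Chi-square of the EFA model and of the independence baseline.

    Uses the Bartlett-corrected ML statistic
    (n - 1 - (2p+5)/6 - 2k/3) * F_ml.  Returns (chi2, df, chi2_baseline,
    df_baseline).
    """
    p, k = loadings.shape
    implied = loadings @ phi @ loadings.T
    np.fill_diagonal(implied, 1.0)
    f = ml_discrepancy(sample_corr, implied)
    chi2 = (n - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0) * f
    df = ((p - k) ** 2 - (p + k)) // 2
    _, logdet_s = np.linalg.slogdet(sample_corr)
    chi2_b = -(n - 1 - (2 * p + 5) / 6.0) * logdet_s
    df_b = p * (p - 1) // 2
    return float(max(chi2, 0.0)), int(df), float(chi2_b), int(df_b)


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% CI for RMSEA by inverting the noncentral chi-square."""
    alpha = (1.0 - level) / 2.0
    scale = df * (n - 1)

    def ncp_for(prob: float) -> float:
        # find lambda with P(X2_{df, lambda} <= chi2) = prob
        if sps.chi2.cdf(chi2, df) < prob:
            return 0.0
        hi = max(chi2, 1.0)
        while sps.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2.0
            if hi > 1e8:
                return hi
        return brentq(lambda lam: sps.ncx2.cdf(chi2, df, lam) - prob, 0.0, hi)

    lo = ncp_for(1.0 - alpha)
    hi = ncp_for(alpha)
    return float(np.sqrt(lo / scale)), float(np.sqrt(hi / scale))


def efa_fit(
    chi2: float,
    df: int,
    n: int,
    baseline_chi2: float,
    baseline_df: int,
) -> dict:
    """TLI and RMSEA (with 90% CI) from chi-square statistics."""
    if df < 1 or n <= 1:
        raise ValueError("df must be >= 1 and n > 1")
    if baseline_df <= df:
        raise ValueError("baseline df must exceed model df")
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    ci = _rmsea_ci(chi2, df, n)
    ratio_b = baseline_chi2 / baseline_df
    ratio_m = chi2 / df
    tli = float((ratio_b - ratio_m) / (ratio_b - 1.0))
    return {
        "chi_square": float(chi2),
        "df": int(df),
        "tli": tli,
        "rmsea": rmsea,
        "rmsea_ci90": ci,
    }


def score_reliability(
    corr: np.ndarray, loadings: np.ndarray, phi: np.ndarray
) -> dict:
    """Multiple R^2 of each factor on the items (regression-score validity)."""
    structure = loadings @ phi
    r2 = np.einsum("if,ij,jf->f", structure, np.linalg.inv(corr), structure)
    r2 = np.clip(r2, 0.0, 1.0)
    return {
        "multiple_r2": r2,
        "correlation_with_factor": np.sqrt(r2),
    }


def factor_scores(
    matrix, solution: FactorSolution
) -> tuple[np.ndarray, dict]:
    """Thurstone regression factor scores and their reliability.

    Scores are computed from standardized item responses using
    W = R^-1 (Lambda Phi); reliability is the multiple R^2 of each factor
    on the items, with its square root reported as the expected
    correlation between estimated and true factor.
    """
    data = _as_data(matrix)
    corr = np.corrcoef(data, rowvar=False)
    if np.linalg.cond(corr) > 1e12:
        raise ValueError("item correlation matrix is singular")
    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    weights = np.linalg.inv(corr) @ (solution.loadings @ solution.phi)
    scores = z @ weights
    return scores, score_reliability(corr, solution.loadings, solution.phi)


def fit_efa(
    matrix,
    n_factors: int,
    n_obs: int | None = None,
    gamma: float = 0.0,
    item_ids: list[str] | None = None,
) -> FactorSolution:
    """Full EFA: PAF extraction, oblimin rotation (if >= 2 factors), fit indices.

    ``matrix`` may be raw participant data (ResponseMatrix or array) or a
    precomputed correlation matrix if ``n_obs`` is given.
    """
    if n_obs is None:
        data = _as_data(matrix)
        n_obs = data.shape[0]
        corr = np.corrcoef(data, rowvar=False)
        if isinstance(matrix, ResponseMatrix) and item_ids is None:
            item_ids = list(matrix.item_ids)
    else:
        corr = _check_corr(matrix)
    p = corr.shape[0]
    if item_ids is None:
        item_ids = [f"IP{i + 1}" for i in range(p)]

    lam, h2, heywood = paf(corr, n_factors)
    if n_factors >= 2:
        lam, phi = oblimin_rotate(lam, gamma=gamma)
    else:
        phi = np.eye(1)
    h2 = np.einsum("if,fg,ig->i", lam, phi, lam)
    ss_per_factor = np.diag(phi @ lam.T @ lam)
    chi2, df, chi2_b, df_b = efa_chi_square(corr, lam, phi, n_obs)
    fit = efa_fit(chi2, df, n_obs, chi2_b, df_b) if df >= 1 else {"chi_square": chi2}
    return FactorSolution(
        loadings=lam,
        phi=phi,
        communalities=h2,
        variance_explained=ss_per_factor / p,
        total_variance_explained=float(h2.sum() / p),
        fit=fit,
        score_reliability=score_reliability(corr, lam, phi),
        item_ids=item_ids,
        heywood=heywood,
    )
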