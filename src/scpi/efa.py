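"""Polychoric exploratory factor analysis of the six binary items.

The construct-validity stage estimates the 6x6 tetrachoric correlation
matrix (the binary special case of the polychoric correlation: each item is
a thresholded latent standard normal), extracts factors with the iterated
principal-factor method, retains factors by the Kaiser eigenvalue-greater-
than-one rule (with a scree table for Cattell's visual check), rotates the
retained loadings obliquely with promax, and reports the pattern matrix with
sub-threshold entries masked for display.

All estimators here are deterministic given their input: the bivariate
normal CDF is evaluated with fixed Gauss-Legendre quadrature, eigenvectors
get a fixed sign convention, and rotation starts from the (deterministic)
varimax solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "bvn_cdf",
    "TetrachoricResult",
    "tetrachoric",
    "tetrachoric_from_data",
    "PolychoricMatrix",
    "polychoric_matrix",
    "iterated_principal_factors",
    "retain_factors",
    "varimax",
    "promax",
    "FactorSolution",
    "fit_efa",
    "variance_explained",
    "mask_loadings",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Uses the identity  Phi2(h,k;rho) = Phi(h)Phi(k) +
    (1/2pi) * int_0^asin(rho) exp(-(h^2 + k^2 - 2 h k sin t)/(2 cos^2 t)) dt,
    whose integrand is smooth, evaluated with 64-point Gauss-Legendre
    quadrature.  Deterministic and accurate to ~1e-14 for |rho| <= 0.9999.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    base = stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 0.0:
        return float(base)
    if rho == 1.0:
        return float(stats.norm.cdf(min(h, k)))
    if rho == -1.0:
        return float(max(0.0, stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0))
    upper = np.arcsin(rho)
    t = 0.5 * upper * (_GL_NODES + 1.0)
    w = 0.5 * np.abs(upper) * _GL_WEIGHTS
    cos2 = np.cos(t) ** 2
    integrand = np.exp(-(h * h + k * k - 2.0 * h * k * np.sin(t)) / (2.0 * cos2))
    corr = np.sign(upper) * np.sum(w * integrand) / (2.0 * np.pi)
    return float(np.clip(base + corr, 0.0, 1.0))


@dataclass(frozen=True)
class TetrachoricResult:
    rho: float
    tau1: float
    tau2: float
    n: int
    degenerate: bool = False
    at_cap: bool = False
    message: str = ""


def _cell_probs(tau1: float, tau2: float, rho: float) -> np.ndarray:
    """2x2 cell probabilities under the thresholded bivariate-normal model.

    Cell [i, j] is P(X = i, Y = j) where X = 1(Z1 > tau1), Y = 1(Z2 > tau2).
    """
    p00 = bvn_cdf(tau1, tau2, rho)
    p0_ = stats.norm.cdf(tau1)
    p_0 = stats.norm.cdf(tau2)
    p01 = p0_ - p00
    p10 = p_0 - p00
    p11 = 1.0 - p0_ - p_0 + p00
    return np.clip(np.array([[p00, p01], [p10, p11]]), 1e-300, 1.0)


def tetrachoric(
    table: np.ndarray,
    cap: float = 0.999,
    continuity: bool = False,
) -> TetrachoricResult:
    """Two-step tetrachoric correlation from a 2x2 contingency table.

    ``table[i, j]`` counts observations with X = i and Y = j (i, j in {0,1};
    cell [1, 1] = both endorsed).  Thresholds come from the marginal probits;
    rho then maximizes the bivariate-normal likelihood of the table.  A zero
    cell drives the MLE to the boundary, so the estimate is capped at
    ``+/- cap`` and flagged; ``continuity=True`` instead adds 0.5 to every
    cell first.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if continuity:
        tab = tab + 0.5
    n = tab.sum()
    if n <= 0:
        raise ValueError("empty table")
    row = tab.sum(axis=1)  # X margins (0, 1)
    col = tab.sum(axis=0)
    if row.min() == 0 or col.min() == 0:
        # a degenerate margin: thresholds infinite, rho unidentified
        sign = float(np.sign(tab[0, 0] * tab[1, 1] - tab[0, 1] * tab[1, 0]))
        return TetrachoricResult(
            np.nan, np.inf, np.inf, int(n), degenerate=True,
            message=f"zero margin; association sign {sign:+.0f}",
        )
    tau1 = float(stats.norm.ppf(row[0] / n))  # P(X = 0) = Phi(tau1)
    tau2 = float(stats.norm.ppf(col[0] / n))

    def nll(rho: float) -> float:
        return -float(np.sum(tab * np.log(_cell_probs(tau1, tau2, rho))))

    res = optimize.minimize_scalar(
        nll, bounds=(-cap, cap), method="bounded",
        options={"xatol": 1e-10},
    )
    rho = float(res.x)
    msg = ""
    if (tab == 0).any():
        # a zero cell pushes the MLE to the boundary; report the signed cap
        rho = float(np.sign(tab[0, 0] * tab[1, 1] - tab[0, 1] * tab[1, 0]) * cap)
        at_cap = True
        msg = "zero cell; estimate at cap"
    elif abs(rho) >= cap - 1e-6:
        at_cap = True
        msg = "estimate at cap"
    else:
        at_cap = False
    if msg:
        warnings.warn(f"tetrachoric: {msg}", stacklevel=2)
    return TetrachoricResult(rho, tau1, tau2, int(n), at_cap=at_cap, message=msg)


def tetrachoric_from_data(x: np.ndarray, y: np.ndarray, **kw) -> TetrachoricResult:
    """Tetrachoric correlation of two 0/1 vectors."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    tab = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            tab[i, j] = np.sum((x == i) & (y == j))
    return tetrachoric(tab, **kw)


@dataclass(frozen=True)
class PolychoricMatrix:
    rho: np.ndarray                      # p x p correlation estimates
    thresholds: np.ndarray               # per-item probit threshold
    diagnostics: pd.DataFrame            # per-pair convergence/cap flags
    item_names: tuple[str, ...] = ()


def polychoric_matrix(items, cap: float = 0.999, continuity: bool = False) -> PolychoricMatrix:
    """Pairwise tetrachoric correlation matrix of binary item columns.

    ``items`` is an (n, p) 0/1 array or a DataFrame of item columns.
    """
    if isinstance(items, pd.DataFrame):
        names = tuple(items.columns)
        X = items.to_numpy(dtype=float)
    else:
        X = np.asarray(items, dtype=float)
        names = tuple(f"item{i}" for i in range(X.shape[1]))
    if np.isnan(X).any():
        X = X[~np.isnan(X).any(axis=1)]
    if not set(np.unique(X)) <= {0.0, 1.0}:
        raise ValueError("items must be coded 0/1")
    n, p = X.shape
    R = np.eye(p)
    taus = stats.norm.ppf(1.0 - X.mean(axis=0))
    diag_rows = []
    for i in range(p):
        for j in range(i + 1, p):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = tetrachoric_from_data(X[:, i], X[:, j], cap=cap, continuity=continuity)
            R[i, j] = R[j, i] = res.rho
            diag_rows.append(
                {"item_i": names[i], "item_j": names[j], "rho": res.rho,
                 "degenerate": res.degenerate, "at_cap": res.at_cap,
                 "message": res.message}
            )
    if np.isnan(R).any():
        raise ValueError("degenerate item pair(s); cannot assemble correlation matrix")
    return PolychoricMatrix(R, taus, pd.DataFrame(diag_rows), names)


# ---------------------------------------------------------------------------
# factor extraction


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    return 0.5 * (R + R.T)


def _principal_loadings(Rred: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-axis loadings of a reduced correlation matrix,
    with a fixed sign convention (largest-|.| element of each vector > 0)."""
    vals, vecs = np.linalg.eigh(Rred)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    vecs_k = vecs[:, order]
    for c in range(vecs_k.shape[1]):
        lead = np.argmax(np.abs(vecs_k[:, c]))
        if vecs_k[lead, c] < 0:
            vecs_k[:, c] *= -1
    return vecs_k * np.sqrt(vals_k)


def smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, the standard initial communalities."""
    Rinv = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(Rinv)


def iterated_principal_factors(
    R: np.ndarray,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
):
    """Iterated principal-factor extraction.

    Starting from SMC communalities, alternate: put the current
    communalities on the diagonal of R, eigen-decompose, rebuild loadings
    from the top-k principal axes, update communalities as row sums of
    squared loadings — until the largest communality change is below ``tol``.
    Communality estimates exceeding 1 (Heywood cases) are clipped with a
    warning.

    Returns ``(loadings, communalities, eigenvalues, n_iter, converged)``
    where ``eigenvalues`` is the full eigenvalue sequence of the final
    reduced matrix, sorted descending.
    """
    R = _check_corr(R)
    p = R.shape[0]
    if not 1 <= k < p:
        raise ValueError(f"number of factors k={k} must satisfy 1 <= k < {p}")
    try:
        h2 = np.clip(smc(R), 0.0, 1.0)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    heywood = False
    n_iter = 0
    converged = False
    L = np.zeros((p, k))
    for n_iter in range(1, max_iter + 1):
        Rred = R.copy()
        np.fill_diagonal(Rred, h2)
        L = _principal_loadings(Rred, k)
        h2_new = np.sum(L**2, axis=1)
        if (h2_new > 1.0).any():
            heywood = True
            h2_new = np.clip(h2_new, 0.0, 1.0)
        delta = np.max(np.abs(h2_new - h2))
        h2 = h2_new
        if delta < tol:
            converged = True
            break
    if heywood:
        warnings.warn("Heywood case: communality clipped at 1", stacklevel=2)
    Rred = R.copy()
    np.fill_diagonal(Rred, h2)
    eigvals = np.sort(np.linalg.eigvalsh(Rred))[::-1]
    return L, h2, eigvals, n_iter, converged


def retain_factors(eigenvalues: np.ndarray) -> tuple[int, pd.DataFrame]:
    """Kaiser retention (count of eigenvalues strictly greater than 1) plus a
    scree table (eigenvalue vs. index with first differences) for Cattell's
    visual check."""
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    k = int(np.sum(ev > 1.0))
    scree = pd.DataFrame(
        {
            "factor": np.arange(1, len(ev) + 1),
            "eigenvalue": ev,
            "first_difference": np.concatenate([[np.nan], -np.diff(ev)]),
            "cumulative_share": np.cumsum(ev) / np.sum(ev) if np.sum(ev) > 0 else np.nan,
        }
    )
    return k, scree


# ---------------------------------------------------------------------------
# rotation


def varimax(
    L: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (SVD algorithm, Kaiser row normalization by default).

    Returns ``(rotated, rotation)`` with ``rotated = L @ rotation``.
    """
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    if normalize:
        norms = np.sqrt(np.sum(L**2, axis=1))
        norms[norms == 0] = 1.0
        A = L / norms[:, None]
    else:
        A = L.copy()
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ T
        u, s, vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag(np.sum(B**2, axis=0)) / p)
        )
        T = u @ vt
        d_new = np.sum(s)
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    rotated = A @ T
    if normalize:
        rotated = rotated * norms[:, None]
    return rotated, T


def promax(
    L: np.ndarray,
    power: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Promax oblique rotation.

    Varimax-rotate, build the element-wise signed power-``power`` target,
    fit an oblique transformation to it by least squares, and rescale its
    columns so the implied factor correlation matrix has a unit diagonal.

    Returns ``(pattern, phi, transform)`` with ``pattern = L @ transform``
    and ``phi`` the factor correlation matrix.  ``pattern @ phi @ pattern.T``
    reproduces exactly what the unrotated ``L @ L.T`` does.
    """
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k == 0:
        return L.copy(), np.eye(0), np.eye(0)
    if k == 1:
        return L.copy(), np.eye(1), np.eye(1)
    V, T_vmx = varimax(L)
    target = V * np.abs(V) ** (power - 1)
    U, *_ = np.linalg.lstsq(V, target, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    phi = np.linalg.inv(U.T @ U)
    phi = 0.5 * (phi + phi.T)
    transform = T_vmx @ U
    pattern = L @ transform
    return pattern, phi, transform


def _order_and_sign(pattern, phi):
    """Order factors by explained variance (SS of structure loadings) and fix
    each column's sign so its largest-magnitude loading is positive."""
    structure = pattern @ phi
    ss = np.sum(structure**2, axis=0)
    order = np.argsort(ss)[::-1]
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.ones(pattern.shape[1])
    for c in range(pattern.shape[1]):
        lead = np.argmax(np.abs(pattern[:, c]))
        if pattern[lead, c] < 0:
            signs[c] = -1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return pattern, phi


@dataclass(frozen=True)
class FactorSolution:
    """Complete EFA output for one correlation matrix."""

    n_factors: int
    loadings_unrotated: np.ndarray
    pattern: np.ndarray                   # promax pattern matrix
    phi: np.ndarray                       # factor correlation matrix
    communalities: np.ndarray
    uniquenesses: np.ndarray
    eigenvalues: np.ndarray               # of the input correlation matrix
    eigenvalues_reduced: np.ndarray       # of the final reduced matrix
    scree: pd.DataFrame
    item_names: tuple[str, ...]
    converged: bool
    n_iter: int
    input_corr: np.ndarray = field(repr=False, default=None)

    @property
    def structure(self) -> np.ndarray:
        return self.pattern @ self.phi


def fit_efa(
    R: np.ndarray | PolychoricMatrix,
    n_factors: int | None = None,
    promax_power: int = 4,
    item_names: tuple[str, ...] | None = None,
) -> FactorSolution:
    """Run the full extraction-retention-rotation cycle on a correlation matrix.

    When ``n_factors`` is None, the Kaiser rule applied to the eigenvalues of
    the input correlation matrix itself decides how many factors to keep.
    """
    if isinstance(R, PolychoricMatrix):
        item_names = item_names or R.item_names
        R = R.rho
    R = _check_corr(R)
    p = R.shape[0]
    names = tuple(item_names) if item_names else tuple(f"item{i}" for i in range(p))
    ev_input = np.sort(np.linalg.eigvalsh(R))[::-1]
    k_kaiser, scree = retain_factors(ev_input)
    k = n_factors if n_factors is not None else k_kaiser
    if k == 0:
        empty = np.zeros((p, 0))
        return FactorSolution(
            0, empty, empty, np.eye(0), np.zeros(p), np.ones(p),
            ev_input, ev_input, scree, names, True, 0, R,
        )
    L, h2, ev_red, n_iter, converged = iterated_principal_factors(R, k)
    pattern, phi, _ = promax(L, power=promax_power)
    pattern, phi = _order_and_sign(pattern, phi)
    return FactorSolution(
        k, L, pattern, phi, h2, 1.0 - h2, ev_input, ev_red, scree,
        names, converged, n_iter, R,
    )


def variance_explained(solution: FactorSolution) -> dict[str, float]:
    """Variance-explained proportions under several conventions.

    ``common_over_total`` (the default headline number) is the share of
    total item variance captured by the common factors, sum(h2)/p.  Also
    reported: the share each rule's numerator makes of common variance only,
    and the rotated sum of squared structure loadings over p.
    """
    p = len(solution.communalities)
    total_h2 = float(np.sum(solution.communalities))
    out = {
        "common_over_total": total_h2 / p,
        "retained_eigenvalues_over_total": float(
            np.sum(np.sort(solution.eigenvalues)[::-1][: solution.n_factors]) / p
        ),
        "structure_ss_over_total": float(np.sum(solution.structure**2) / p)
        if solution.n_factors
        else 0.0,
    }
    return out


def mask_loadings(
    pattern: np.ndarray,
    threshold: float = 0.50,
    item_names: tuple[str, ...] | None = None,
    fmt: str = "{:.2f}",
) -> pd.DataFrame:
    """Display table with |loading| < threshold blanked.

    The full-precision matrix is what the machine-readable outputs carry;
    this masked view is for reports only.
    """
    P = np.asarray(pattern, dtype=float)
    p, k = P.shape
    names = item_names or tuple(f"item{i}" for i in range(p))
    rows = []
    for i in range(p):
        row = {}
        for j in range(k):
            row[f"factor_{j + 1}"] = (
                fmt.format(P[i, j]) if abs(P[i, j]) >= threshold else ""
            )
        rows.append(row)
        if k and all(v == "" for v in row.values()):
            warnings.warn(
                f"item {names[i]!r}: no loading reaches |{threshold}|", stacklevel=2
            )
    return pd.DataFrame(rows, index=list(names))
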