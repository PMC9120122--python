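"""Non-metric multidimensional scaling (NMDS) and envfit.

NMDS embeds a site dissimilarity matrix (here Bray-Curtis) in ``k``
dimensions so that configuration distances preserve the *rank order* of the
dissimilarities.  The loss is Kruskal's stress-1,

.. math:: \\mathrm{stress} = \\sqrt{\\frac{\\sum_{i<j}(d_{ij}-\\hat d_{ij})^2}
                                      {\\sum_{i<j} d_{ij}^2}}

where :math:`d` are configuration distances and :math:`\\hat d` the isotonic
(monotone in the dissimilarity ranks) fitted values.  Optimisation is
iterative majorisation (SMACOF) with an isotonic step each iteration and
multiple random starts; ties in the dissimilarities receive the primary
("weak") treatment.  The best configuration is centred and rotated to its
principal axes so axis 1 carries maximal variance.

``envfit`` regresses each (centred) environmental variable on the ordination
scores; the arrow direction is the normalised coefficient vector, r² the
squared multiple correlation, and significance comes from permuting the
variable's values across sites with the add-one Monte-Carlo estimator
p = (1 + #{r²* >= r²}) / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

__all__ = ["OrdinationResult", "EnvFitResult", "isotonic_fit", "nmds", "envfit"]


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # sites x k, centred, principal-axis rotated
    stress: float
    n_starts_used: int
    converged: bool
    best_seed: int

    @property
    def site_ids(self):
        return list(self.scores.index)


@dataclass
class EnvFitResult:
    table: pd.DataFrame  # per variable: dir1..dirk, r2, p_perm, n_perm
    n_perm: int

    def significant(self, alpha: float = 0.05) -> list:
        t = self.table
        return list(t.index[t["p_perm"] < alpha])


def isotonic_fit(d_config: np.ndarray, order_of_d: np.ndarray) -> np.ndarray:
    """Least-squares monotone (PAVA) fit of ``d_config`` against a rank order.

    Returns the isotonic regression of the configuration distances taken in
    the order given by ``order_of_d`` (ranks of the dissimilarities), mapped
    back to the original positions.  Piecewise constant; preserves the mean.
    """
    d = np.asarray(d_config, dtype=float)
    r = np.asarray(order_of_d)
    if d.size == 0:
        raise ValueError("empty input")
    if d.shape != r.shape:
        raise ValueError("d_config and order_of_d must have equal length")
    idx = np.argsort(r, kind="stable")
    fit_sorted = isotonic_regression(d[idx])
    out = np.empty_like(d)
    out[idx] = fit_sorted
    return out


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _smacof_single(
    delta: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, float]:
    n = delta.shape[0]
    iu = np.triu_indices(n, 1)
    delta_cond = delta[iu]
    x = rng.normal(size=(n, k)) * np.mean(delta_cond)
    prev = np.inf
    stress = np.inf
    for _ in range(max_iter):
        d_cond = pdist(x)
        # primary ties: within tied dissimilarities, order by current d so
        # no monotonicity constraint applies inside a tie block
        order = np.lexsort((d_cond, delta_cond))
        dhat_sorted = isotonic_regression(d_cond[order])
        dhat = np.empty_like(d_cond)
        dhat[order] = dhat_sorted
        stress = _stress1(d_cond, dhat)
        if prev - stress < tol:
            break
        prev = stress
        # Guttman transform toward the disparities
        d_mat = squareform(d_cond)
        dhat_mat = squareform(dhat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_mat > 0, dhat_mat / np.where(d_mat > 0, d_mat, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
    return x, stress


def _procrustes_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """RMSE between two configurations after centring, unit-scaling and an
    optimal orthogonal rotation of b onto a."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    a, b = a / na, b / nb
    u, _, vt = np.linalg.svd(a.T @ b)
    rot = (u @ vt).T
    return float(np.sqrt(np.mean((a - b @ rot) ** 2)))


def nmds(
    dissimilarity: pd.DataFrame,
    k: int = 2,
    n_starts: int = 100,
    max_iter: int = 300,
    tol: float = 1e-10,
    seed: int = 0,
    stability_rmse: float = 1e-4,
) -> OrdinationResult:
    """Multi-start NMDS of a symmetric dissimilarity matrix.

    Runs ``n_starts`` SMACOF searches from random configurations, keeps the
    lowest-stress solution, and declares it stable ("converged") when the
    two best starts agree to a Procrustes RMSE below ``stability_rmse``.
    Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if isinstance(dissimilarity, pd.DataFrame):
        ids = list(dissimilarity.index)
        delta = dissimilarity.to_numpy(dtype=float)
    else:
        delta = np.asarray(dissimilarity, dtype=float)
        ids = list(range(delta.shape[0]))
    if delta.ndim != 2 or delta.shape[0] != delta.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(delta, delta.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = delta.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k+1} sites, got {n}")

    root = np.random.default_rng(seed)
    runs: list[tuple[float, int, np.ndarray]] = []
    for start in range(n_starts):
        x, stress = _smacof_single(delta, k, root, max_iter, tol)
        runs.append((stress, start, x))
    runs.sort(key=lambda t: (t[0], t[1]))
    best_stress, best_start, best_x = runs[0]
    if len(runs) > 1:
        converged = _procrustes_rmse(best_x, runs[1][2]) < stability_rmse
    else:
        converged = True

    # centre and rotate to principal axes (reproducible orientation)
    x = best_x - best_x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    # fix signs so the largest-magnitude loading on each axis is positive
    x = x @ vt.T
    for j in range(x.shape[1]):
        if x[np.argmax(np.abs(x[:, j])), j] < 0:
            x[:, j] = -x[:, j]
    scores = pd.DataFrame(x, index=ids, columns=[f"NMDS{i+1}" for i in range(k)])
    return OrdinationResult(scores, best_stress, n_starts, converged, best_start)


def envfit(
    ordination: OrdinationResult | pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 99_999,
    seed: int = 0,
) -> EnvFitResult:
    """Fit environmental vectors onto ordination scores with permutation
    significance (add-one Monte-Carlo p-values).

    Constant variables are reported with NaN statistics and a warning rather
    than aborting the remaining fits.
    """
    scores = ordination.scores if isinstance(ordination, OrdinationResult) else ordination
    if not scores.index.equals(env.index):
        env = env.loc[scores.index]  # raises on missing sites
    s = scores.to_numpy(dtype=float)
    s = s - s.mean(axis=0)
    n, k = s.shape
    # hat projector onto the score space
    h = s @ np.linalg.pinv(s.T @ s) @ s.T
    rng = np.random.default_rng(seed)
    rows = {}
    for var in env.columns:
        y = env[var].to_numpy(dtype=float)
        yc = y - y.mean()
        tss = float(yc @ yc)
        if tss == 0:
            warnings.warn(f"envfit: variable {var!r} is constant; skipped")
            rows[var] = dict(
                {f"dir{i+1}": np.nan for i in range(k)}, r2=np.nan, p_perm=np.nan, n_perm=n_perm
            )
            continue
        coef = np.linalg.lstsq(s, yc, rcond=None)[0]
        fitted = h @ yc
        r2 = float(fitted @ fitted) / tss
        direction = coef / np.linalg.norm(coef) if np.linalg.norm(coef) > 0 else coef
        # vectorised permutation null: rows of yp are permuted copies of y
        perm = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        perm = perm - perm.mean(axis=1, keepdims=True)
        num = np.einsum("ij,ij->j", h @ perm.T, perm.T)
        den = np.einsum("ij,ij->i", perm, perm)
        r2_null = num / den
        p = (1.0 + np.sum(r2_null >= r2 - 1e-12)) / (n_perm + 1.0)
        rows[var] = dict(
            {f"dir{i+1}": direction[i] for i in range(k)}, r2=r2, p_perm=p, n_perm=n_perm
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    return EnvFitResult(table, n_perm)
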