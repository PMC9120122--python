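"""RLQ ordination and fourth-corner trait-environment analysis.

The three tables are the site x environment matrix **R**, the site x species
abundance matrix **L** and the species x trait matrix **Q**.  With
``P = L / grand total``, row weights ``r`` (site weights, row sums of P) and
column weights ``c`` (species weights, column sums of P), environment and
coded trait columns are standardised under their weight metrics and the
cross-matrix

.. math:: M = \\tilde R^T (P - r c^T) \\tilde Q

holds the fourth-corner pseudo-correlations between every environmental
variable and every coded trait column (``|M_kt| <= 1``).  RLQ axes are the
singular vectors of M; eigenvalues are squared singular values.

Significance uses permutation model 2: the rows of L are permuted, breaking
the site-environment link while keeping the species-trait link, with the
weights recomputed for every permutation and a two-sided add-one
Monte-Carlo p-value per (environment, trait) pair.

The direction of significant associations is double-checked with Poisson
GLMs of per-site trait-level species counts on each environmental variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "code_traits",
    "rlq",
    "fourth_corner",
    "trait_counts_per_site",
    "trait_direction_glm",
    "trait_directions",
    "RLQResult",
    "FourthCornerResult",
    "TraitDirectionResult",
]


def _is_categorical(col: pd.Series) -> bool:
    return col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)


def code_traits(
    traits: pd.DataFrame,
    species_weights: pd.Series | np.ndarray | None = None,
    standardize_quantitative: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a trait table into a numeric coded matrix.

    Categorical traits become one 0/1 column per level (named
    ``trait:level``); quantitative traits are z-scored under the species
    weights (column totals of L over the grand total; uniform if omitted).
    Single-level categoricals and zero-variance quantitative columns are
    dropped with a warning.

    Returns ``(coded, meta)`` where ``meta`` has one row per coded column
    with its source trait and level (NaN for quantitative).
    """
    if traits.isna().any().any():
        raise ValueError("trait table contains missing values")
    n = len(traits)
    if species_weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(
            species_weights.loc[traits.index] if isinstance(species_weights, pd.Series)
            else species_weights,
            dtype=float,
        )
        w = w / w.sum()
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for trait in traits.columns:
        col = traits[trait]
        if _is_categorical(col):
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                warnings.warn(f"trait {trait!r} has a single level; dropped")
                continue
            for lev in levels:
                name = f"{trait}:{lev}"
                cols[name] = (col.astype(str) == lev).to_numpy(dtype=float)
                meta_rows.append({"coded_col": name, "trait": trait, "level": lev})
        else:
            v = col.to_numpy(dtype=float)
            if standardize_quantitative:
                mu = float(w @ v)
                sd = float(np.sqrt(w @ (v - mu) ** 2))
                if sd == 0:
                    warnings.warn(f"trait {trait!r} is constant; dropped")
                    continue
                v = (v - mu) / sd
            elif np.all(v == v[0]):
                warnings.warn(f"trait {trait!r} is constant; dropped")
                continue
            cols[trait] = v
            meta_rows.append({"coded_col": trait, "trait": trait, "level": np.nan})
    coded = pd.DataFrame(cols, index=traits.index)
    meta = pd.DataFrame(meta_rows)
    return coded, meta


def _weighted_standardize(x: np.ndarray, w: np.ndarray, label: str = "column") -> np.ndarray:
    """Standardise columns of x to weighted mean 0, weighted sd 1."""
    mu = w @ x
    xc = x - mu
    sd = np.sqrt(w @ xc**2)
    if np.any(sd == 0):
        raise ValueError(f"degenerate {label}: zero weighted variance")
    return xc / sd


def _cross_matrix(
    r_mat: np.ndarray, p: np.ndarray, q_mat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourth-corner cross matrix M plus the standardised R and Q used."""
    rw = p.sum(axis=1)
    cw = p.sum(axis=0)
    x = _weighted_standardize(r_mat, rw, "environment variable")
    z = _weighted_standardize(q_mat, cw, "trait column")
    m = x.T @ (p - np.outer(rw, cw)) @ z
    return m, x, z


def _align(r: pd.DataFrame, l: pd.DataFrame, q: pd.DataFrame) -> None:
    if not r.index.equals(l.index):
        raise ValueError("R and L site identifiers differ")
    if not l.columns.equals(q.index):
        raise ValueError("L species identifiers and Q rows differ")


@dataclass
class RLQResult:
    eigenvalues: np.ndarray
    env_loadings: pd.DataFrame
    trait_loadings: pd.DataFrame
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame


def rlq(r: pd.DataFrame, l: pd.DataFrame, q_coded: pd.DataFrame) -> RLQResult:
    """RLQ decomposition of the weighted trait-environment cross matrix.

    ``q_coded`` is the numeric coded trait matrix from :func:`code_traits`.
    Eigenvalues are the squared singular values of M; the first equals the
    maximal squared fourth-corner statistic achievable by any pair of unit
    linear combinations of environment and trait columns.
    """
    _align(r, l, q_coded)
    lv = l.to_numpy(dtype=float)
    tot = lv.sum()
    if tot <= 0:
        raise ValueError("L matrix has zero grand total")
    p = lv / tot
    m, _, _ = _cross_matrix(r.to_numpy(dtype=float), p, q_coded.to_numpy(dtype=float))
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    if np.allclose(s, 0):
        raise ValueError("degenerate structure: cross matrix has rank 0")
    axes = [f"AxisR{i+1}" for i in range(len(s))]
    rw = p.sum(axis=1)
    cw = p.sum(axis=0)
    x = _weighted_standardize(r.to_numpy(dtype=float), rw)
    z = _weighted_standardize(q_coded.to_numpy(dtype=float), cw)
    return RLQResult(
        eigenvalues=s**2,
        env_loadings=pd.DataFrame(u, index=r.columns, columns=axes),
        trait_loadings=pd.DataFrame(vt.T, index=q_coded.columns, columns=axes),
        site_scores=pd.DataFrame(x @ u, index=r.index, columns=axes),
        species_scores=pd.DataFrame(z @ vt.T, index=q_coded.index, columns=axes),
    )


@dataclass
class FourthCornerResult:
    table: pd.DataFrame  # index (env, coded trait col): stat, p_perm, sign
    n_perm: int
    model_id: int
    n_resampled: int = 0

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_perm"] < alpha]


def fourth_corner(
    r: pd.DataFrame,
    l: pd.DataFrame,
    q_coded: pd.DataFrame,
    n_perm: int = 9_999,
    model: int = 2,
    seed: int = 0,
    max_resample: int = 100,
) -> FourthCornerResult:
    """Fourth-corner permutation test of every (environment, trait) pair.

    Model 2 permutes the rows of L (detaching sites from their environment)
    and recomputes the site weights for every permutation.  p-values are
    two-sided add-one Monte-Carlo on |stat|.  A permutation that degenerates
    a standardisation (possible only in pathological weightings) is redrawn,
    up to ``max_resample`` times in total.
    """
    if model != 2:
        raise NotImplementedError("only permutation model 2 (rows of L) is implemented")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    _align(r, l, q_coded)
    lv = l.to_numpy(dtype=float)
    tot = lv.sum()
    if tot <= 0:
        raise ValueError("L matrix has zero grand total")
    p = lv / tot
    rv = r.to_numpy(dtype=float)
    qv = q_coded.to_numpy(dtype=float)
    m_obs, _, _ = _cross_matrix(rv, p, qv)

    rng = np.random.default_rng(seed)
    n_sites = p.shape[0]
    exceed = np.zeros_like(m_obs)
    resampled = 0
    done = 0
    while done < n_perm:
        perm = rng.permutation(n_sites)
        try:
            m_perm, _, _ = _cross_matrix(rv, p[perm], qv)
        except ValueError:
            resampled += 1
            if resampled > max_resample:
                raise ValueError("too many degenerate permutations") from None
            continue
        exceed += np.abs(m_perm) >= np.abs(m_obs) - 1e-12
        done += 1
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    for ki, env_var in enumerate(r.columns):
        for ti, tcol in enumerate(q_coded.columns):
            stat = m_obs[ki, ti]
            rows.append(
                {
                    "env": env_var,
                    "trait": tcol,
                    "stat": stat,
                    "p_perm": pvals[ki, ti],
                    "sign": "+" if stat > 0 else ("-" if stat < 0 else "0"),
                }
            )
    table = pd.DataFrame(rows).set_index(["env", "trait"])
    return FourthCornerResult(table, n_perm, model, resampled)


def trait_counts_per_site(l: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Count, per site, the species present that carry each categorical
    trait level.  Quantitative traits are excluded (the GLM direction check
    applies to categorical levels)."""
    if not l.columns.equals(traits.index):
        raise ValueError("L species identifiers and trait rows differ")
    presence = (l.to_numpy(dtype=float) > 0).astype(float)
    cols = {}
    for trait in traits.columns:
        col = traits[trait]
        if not _is_categorical(col):
            continue
        for lev in sorted(col.astype(str).unique()):
            indicator = (col.astype(str) == lev).to_numpy(dtype=float)
            cols[f"{trait}:{lev}"] = presence @ indicator
    return pd.DataFrame(cols, index=l.index)


@dataclass
class TraitDirectionResult:
    beta: float
    se: float
    z: float
    p_wald: float
    sign: str
    converged: bool


def trait_direction_glm(counts, env_var) -> TraitDirectionResult:
    """Poisson log-link GLM of a per-site trait count on one environmental
    variable; returns the slope with Wald inference and its sign."""
    y = np.asarray(counts, dtype=float)
    x = np.asarray(env_var, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if not np.all(np.isfinite(x)):
        raise ValueError("environmental variable must be finite")
    if np.all(y == 0):
        raise ValueError("all-zero counts: Poisson GLM undefined")
    design = sm.add_constant(x)
    model = sm.GLM(y, design, family=sm.families.Poisson())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(maxiter=100, tol=1e-10)
            converged = bool(fit.converged)
        except Exception:
            fit = model.fit(maxiter=500, method="lbfgs")
            converged = False
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    zval = beta / se if se > 0 else np.nan
    pval = float(fit.pvalues[1])
    sign = "+" if beta > 0 else ("-" if beta < 0 else "0")
    return TraitDirectionResult(beta, se, zval, pval, sign, converged)


def trait_directions(trait_counts: pd.DataFrame, env: pd.DataFrame) -> pd.DataFrame:
    """GLM direction check for every (trait level, environment) pair.

    Long-format table indexed by (env, trait); levels whose counts are all
    zero are skipped."""
    if not trait_counts.index.equals(env.index):
        raise ValueError("site identifiers differ between counts and environment")
    rows = []
    for tcol in trait_counts.columns:
        y = trait_counts[tcol]
        if (y == 0).all():
            continue
        for var in env.columns:
            res = trait_direction_glm(y, env[var])
            rows.append(
                {
                    "env": var,
                    "trait": tcol,
                    "beta": res.beta,
                    "se": res.se,
                    "z": res.z,
                    "p_wald": res.p_wald,
                    "sign": res.sign,
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows).set_index(["env", "trait"])
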