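"""Dufrêne-Legendre indicator species analysis (IndVal).

For a site classification (here the low/medium/high urbanisation or
connectivity classes) and a species *s*:

* specificity ``A[s,c]`` — mean abundance of *s* in class *c* divided by the
  sum of its mean abundances over all classes (group-size corrected
  "relative average abundance");
* fidelity ``B[s,c]`` — proportion of the sites of class *c* in which *s*
  is present ("relative frequency");
* ``IV = A * B``, in [0, 1]; 1 means the species occurs in every site of
  one class and nowhere else.

Species whose best IV reaches a threshold (0.3 by default) are declared
indicator species for their best class.  An optional site-permutation test
is provided but the threshold rule alone is the default selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import validate_community

__all__ = ["IndValTable", "indval", "select_indicators", "indval_permutation_test"]


@dataclass
class IndValTable:
    A: pd.DataFrame  # species x class specificity
    B: pd.DataFrame  # species x class fidelity
    IV: pd.DataFrame  # species x class indicator values
    best: pd.DataFrame  # per species: best_class (ties joined by '|'), best_IV

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (species, class)."""
        rows = []
        for sp in self.IV.index:
            for cls in self.IV.columns:
                rows.append(
                    {
                        "species": sp,
                        "class": cls,
                        "A": self.A.loc[sp, cls],
                        "B": self.B.loc[sp, cls],
                        "IV": self.IV.loc[sp, cls],
                    }
                )
        return pd.DataFrame(rows)


def _class_arrays(matrix: pd.DataFrame, classes: pd.Series | dict) -> tuple[pd.Series, list]:
    classes = pd.Series(classes)
    missing = [s for s in matrix.index if s not in classes.index]
    if missing:
        raise ValueError(f"sites without a class label: {missing}")
    classes = classes.loc[matrix.index]
    levels = sorted(classes.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 classes")
    return classes, levels


def indval(matrix: pd.DataFrame, classes: pd.Series | dict) -> IndValTable:
    """Indicator values of every species for every site class.

    ``classes`` maps each site of ``matrix`` to a class label; every class
    must contain at least one site.
    """
    validate_community(matrix)
    classes, levels = _class_arrays(matrix, classes)
    x = matrix.to_numpy(dtype=float)
    mean_ab = np.empty((x.shape[1], len(levels)))
    freq = np.empty_like(mean_ab)
    for c, lev in enumerate(levels):
        mask = (classes == lev).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"class {lev!r} has no sites")
        mean_ab[:, c] = x[mask].mean(axis=0)
        freq[:, c] = (x[mask] > 0).mean(axis=0)
    denom = mean_ab.sum(axis=1)
    a = np.divide(mean_ab, denom[:, None], out=np.zeros_like(mean_ab), where=denom[:, None] > 0)
    iv = a * freq
    A = pd.DataFrame(a, index=matrix.columns, columns=levels)
    B = pd.DataFrame(freq, index=matrix.columns, columns=levels)
    IV = pd.DataFrame(iv, index=matrix.columns, columns=levels)
    best_iv = IV.max(axis=1)
    best_class = IV.apply(
        lambda row: "|".join(IV.columns[np.isclose(row, row.max())]), axis=1
    )
    best = pd.DataFrame({"best_class": best_class, "best_IV": best_iv})
    return IndValTable(A, B, IV, best)


def select_indicators(table: IndValTable, threshold: float = 0.3) -> pd.DataFrame:
    """Species whose best IV is >= ``threshold`` (boundary included), sorted
    by IV descending. Columns: species, class, IV."""
    sel = table.best[table.best["best_IV"] >= threshold].copy()
    sel = sel.sort_values("best_IV", ascending=False)
    return pd.DataFrame(
        {"species": sel.index, "class": sel["best_class"].values, "IV": sel["best_IV"].values}
    ).reset_index(drop=True)


def indval_permutation_test(
    matrix: pd.DataFrame, classes: pd.Series | dict, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Optional site-label permutation test of each species' best IV
    (add-one Monte-Carlo p-values); off by default in the pipeline."""
    obs = indval(matrix, classes)
    classes = pd.Series(classes).loc[matrix.index]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(matrix.shape[1])
    labels = classes.to_numpy()
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(labels), index=matrix.index)
        best = indval(matrix, perm).best["best_IV"].to_numpy()
        exceed += best >= obs.best["best_IV"].to_numpy() - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    out = obs.best.copy()
    out["p_perm"] = p
    return out
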