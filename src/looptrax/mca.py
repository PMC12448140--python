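"""Multiple correspondence analysis of categorical cohorts, from first principles.

MCA is correspondence analysis of the complete disjunctive (indicator)
matrix Z (n individuals x J levels over Q variables).  With correspondence
matrix P = Z / (nQ), row masses r_i = 1/n and column masses c_j = n_j/(nQ),
the standardized residual matrix

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

is decomposed by SVD, S = U Sigma V^T.  Eigenvalues are the squared singular
values; total inertia obeys the closed-form identity sum(lambda) = (J-Q)/Q.
Individuals and levels are reported in principal coordinates
(F = D_r^{-1/2} U Sigma, G = D_c^{-1/2} V Sigma).  Per dimension the
contribution of level j is 100 * c_j * g_jk^2 / lambda_k, summing to 100.
The v-test of a level on a dimension scales the mean individual coordinate
of the carriers by sqrt(n_j (n-1) / (n - n_j)) / sigma_k; it behaves as a
Z score, so |v| > 2 flags a strong association between the level and the
dimension.  Records with unknown levels are excluded upstream (no
imputation); each dimension's sign is canonicalized so the level of largest
absolute coordinate is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import Cohort

__all__ = ["MCAResult", "mca_fit", "mca_project_plot_data"]


@dataclass(frozen=True)
class MCAResult:
    eigenvalues: np.ndarray  # full non-trivial spectrum; sums to (J - Q)/Q
    singular_values: np.ndarray
    row_coords: pd.DataFrame  # n x d, principal coordinates, index = subject ids
    col_coords: pd.DataFrame  # J x d, index = "variable=level"
    contributions: pd.DataFrame  # J x d, percent, columns sum to 100
    v_tests: pd.DataFrame  # J x d signed scores
    n: int
    Q: int  # number of variables
    J: int  # total observed levels
    total_inertia: float
    variables: tuple[str, ...]

    @property
    def explained_inertia(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia


def _indicator(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols: list[str] = []
    blocks = []
    for var in df.columns:
        levels = sorted(df[var].unique())
        if len(levels) < 2:
            raise ValueError(f"variable {var!r} is constant among included records")
        block = np.zeros((len(df), len(levels)))
        for k, lev in enumerate(levels):
            block[:, k] = (df[var] == lev).to_numpy(float)
            cols.append(f"{var}={lev}")
        blocks.append(block)
    return np.hstack(blocks), cols


def mca_fit(cohort: Cohort, variables: Sequence[str], n_dims: int = 5) -> MCAResult:
    """Fit an indicator-matrix MCA on the given categorical variables.

    Every included record must carry a known level for every variable
    (filter the cohort first); each variable must show at least two levels.
    Returns up to ``n_dims`` non-trivial dimensions.
    """
    data = {}
    for var in variables:
        vs = cohort.schema[var]
        column = cohort.feature_column(var)
        for i, value in enumerate(column):
            if not vs.is_known(value):
                raise ValueError(
                    f"record {cohort.records[i].subject_id!r} has unknown level for {var!r}; "
                    "apply filter_analysis_set first"
                )
        data[var] = column
    df = pd.DataFrame(data, index=[r.subject_id for r in cohort.records])
    n, Q = len(df), len(variables)
    if n < 3:
        raise ValueError("need at least three records")

    Z, level_names = _indicator(df)
    J = Z.shape[1]
    total = Z.sum()  # n * Q
    P = Z / total
    r = P.sum(axis=1)  # = 1/n each
    c = P.sum(axis=0)  # level masses
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    keep = sv > 1e-12
    sv_all = sv[keep]
    eig_all = sv_all**2  # the full spectrum: sum equals (J - Q) / Q
    d = min(n_dims, sv_all.size)
    sv, U, Vt = sv_all[:d], U[:, keep][:, :d], Vt[keep, :][:d, :]
    eig = eig_all[:d]

    F = (U * sv) / np.sqrt(r)[:, None]  # individual principal coordinates
    G = (Vt.T * sv) / np.sqrt(c)[:, None]  # level principal coordinates

    # canonical sign: per dimension, the largest-|coordinate| level is positive
    for k in range(d):
        j = int(np.argmax(np.abs(G[:, k])))
        if G[j, k] < 0:
            G[:, k] *= -1
            F[:, k] *= -1

    contrib = 100.0 * c[:, None] * G**2 / eig[None, :]

    level_counts = Z.sum(axis=0)
    v = np.zeros_like(G)
    for j in range(J):
        carriers = Z[:, j] > 0
        n_j = level_counts[j]
        if n_j >= n:  # constant level cannot happen (>=2 levels/variable) but guard anyway
            continue
        mean_coord = F[carriers].mean(axis=0)
        v[j] = mean_coord * np.sqrt(n_j * (n - 1) / (n - n_j)) / sv

    dims = [f"dim{k + 1}" for k in range(d)]
    return MCAResult(
        eigenvalues=eig_all,
        singular_values=sv_all,
        row_coords=pd.DataFrame(F, index=df.index, columns=dims),
        col_coords=pd.DataFrame(G, index=level_names, columns=dims),
        contributions=pd.DataFrame(contrib, index=level_names, columns=dims),
        v_tests=pd.DataFrame(v, index=level_names, columns=dims),
        n=n,
        Q=Q,
        J=J,
        total_inertia=(J - Q) / Q,
        variables=tuple(variables),
    )


def mca_project_plot_data(
    result: MCAResult,
    cohort: Cohort,
    color_by: str,
    dims: tuple[int, int] = (1, 2),
) -> pd.DataFrame:
    """Per-individual scatter export: two principal coordinates plus a label.

    ``dims`` are 1-based dimension indices; ``color_by`` may be any schema
    variable (e.g. looping class, or a trajectory-group column added by the
    caller).
    """
    for dim in dims:
        if not 1 <= dim <= result.row_coords.shape[1]:
            raise ValueError(f"dimension {dim} outside the fitted range")
    if color_by not in cohort.schema:
        raise KeyError(f"unknown variable {color_by!r}")
    labels = pd.Series(
        cohort.feature_column(color_by), index=[r.subject_id for r in cohort.records]
    )
    out = result.row_coords.iloc[:, [dims[0] - 1, dims[1] - 1]].copy()
    out.columns = [f"dim{dims[0]}", f"dim{dims[1]}"]
    out[color_by] = labels.reindex(out.index)
    out.index.name = "subject_id"
    return out
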