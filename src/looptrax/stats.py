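"""Exact categorical association testing with multiplicity control.

The cohort analyses rest on the Fisher exact test: 2x2 tables are handled by
direct hypergeometric enumeration; r x c tables by exact enumeration over
all tables with the observed margins when the table space is small enough,
otherwise by Monte Carlo sampling of the permutation null.  The two-sided
p-value is the standard "as or less probable" convention: the sum of the
probabilities of all margin-compatible tables whose conditional probability
does not exceed that of the observed table.  Scan-level multiplicity is
controlled with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .cohort_io import Cohort

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "AssociationResult",
    "fisher_exact",
    "bh_adjust",
    "pairwise_scan",
    "chi_square_gof",
    "sankey_flows",
]

#: tables with more candidate fillings than this fall back to Monte Carlo
DEFAULT_ENUMERATION_BUDGET = 10_000_000
DEFAULT_MC_REPLICATES = 100_000
#: relative tolerance when comparing table probabilities to the observed one,
#: so ties are not lost to floating-point rounding (same role as R's eps)
PROB_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Integer cross-tabulation with labelled rows and columns."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    row_variable: str = ""
    col_variable: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2D matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match the count matrix")

    @classmethod
    def from_pairs(
        cls,
        rows: Sequence[str],
        cols: Sequence[str],
        row_variable: str = "",
        col_variable: str = "",
    ) -> "ContingencyTable":
        """Cross-tabulate paired category labels, dropping empty levels."""
        tab = pd.crosstab(pd.Series(rows), pd.Series(cols))
        tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
        return cls(
            counts=tab.to_numpy(),
            row_labels=tuple(str(x) for x in tab.index),
            col_labels=tuple(str(x) for x in tab.columns),
            row_variable=row_variable,
            col_variable=col_variable,
        )

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str  # "exact-2x2" | "exact-enumeration" | "monte-carlo"
    mc_replicates: int | None = None
    mc_standard_error: float | None = None
    seed: int | None = None


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    table: ContingencyTable
    p_raw: float
    p_adjusted: float
    n_used: int
    test: FisherResult = field(repr=False, default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Fisher exact


def _log_table_prob(counts: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - gammaln(counts + 1).sum()


def _fisher_2x2(counts: np.ndarray) -> float:
    """Two-sided 2x2 Fisher p by hypergeometric enumeration."""
    r1, r2 = counts.sum(axis=1)
    c1, _ = counts.sum(axis=0)
    n = counts.sum()
    const = (
        gammaln(r1 + 1) + gammaln(r2 + 1)
        + gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1)
    )

    def logp(a: int) -> float:
        cells = np.array([a, r1 - a, c1 - a, n - r1 - c1 + a], dtype=float)
        return const - gammaln(cells + 1).sum()

    lp_obs = logp(counts[0, 0])
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = 0.0
    for a in range(lo, hi + 1):
        lp = logp(a)
        if lp <= lp_obs + PROB_RTOL:
            total += math.exp(lp)
    return min(1.0, total)


def _enumeration_bound(row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    """Cheap upper bound on the number of margin-compatible tables."""
    bound = 1.0
    for r in row_sums[:-1]:
        for c in col_sums[:-1]:
            bound *= min(r, c) + 1
            if bound > 1e15:
                return bound
    return bound


def _fisher_rxc_exact(counts: np.ndarray) -> float:
    """Exact r x c Fisher p by recursive enumeration of fixed-margin tables."""
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = counts.sum()
    const = float(gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1))
    lp_obs = _log_table_prob(counts.astype(float), const)
    threshold = lp_obs + PROB_RTOL
    r, c = counts.shape

    total = 0.0
    cell_lg = gammaln(np.arange(n + 2))  # lgamma(k+1) lookup

    def recurse(row: int, col_remaining: np.ndarray, log_acc: float) -> None:
        nonlocal total
        if row == r - 1:
            # last row forced by the column margins
            lp = log_acc - cell_lg[col_remaining + 1].sum()
            if lp <= threshold:
                total += math.exp(lp)
            return
        target = row_sums[row]

        def fill(col: int, remaining: int, rem_cols: np.ndarray, acc: float) -> None:
            if col == c - 1:
                if remaining <= rem_cols[col]:
                    nxt = rem_cols.copy()
                    nxt[col] -= remaining
                    recurse(row + 1, nxt, acc - cell_lg[remaining + 1])
                return
            hi = min(remaining, rem_cols[col])
            for v in range(hi + 1):
                nxt = rem_cols.copy()
                nxt[col] -= v
                fill(col + 1, remaining - v, nxt, acc - cell_lg[v + 1])

        fill(0, int(target), col_remaining, log_acc)

    recurse(0, col_sums.copy(), const)
    return min(1.0, total)


def _fisher_monte_carlo(
    counts: np.ndarray, replicates: int, seed: int | None
) -> tuple[float, float]:
    """Monte Carlo p: permute one margin's labels, score 'as or less probable' tables."""
    rng = np.random.default_rng(seed)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = counts.sum()
    const = float(gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1))
    lp_obs = _log_table_prob(counts.astype(float), const)
    threshold = lp_obs + PROB_RTOL

    rows = np.repeat(np.arange(len(row_sums)), row_sums)
    cols = np.repeat(np.arange(len(col_sums)), col_sums)
    r, c = counts.shape
    hits = 0
    for _ in range(replicates):
        perm = rng.permutation(cols)
        table = np.zeros((r, c), dtype=np.int64)
        np.add.at(table, (rows, perm), 1)
        if _log_table_prob(table.astype(float), const) <= threshold:
            hits += 1
    p = (1 + hits) / (replicates + 1)
    se = math.sqrt(p * (1 - p) / replicates)
    return p, se


def fisher_exact(
    table: ContingencyTable,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int | None = None,
    enumeration_budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> FisherResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    2x2 tables always take the exact hypergeometric path.  Larger tables are
    enumerated exactly while the (bounded) number of margin-compatible
    tables stays under ``enumeration_budget``; beyond it a Monte Carlo
    estimate with ``mc_replicates`` permutations is returned, with its
    standard error and seed recorded in the result metadata.  A degenerate
    table (some margin entirely zero after level dropping, or fewer than two
    rows/columns) yields p = 1 with a warning.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any() or (
        counts.sum(axis=0) == 0
    ).any():
        warnings.warn("degenerate contingency table; association p set to 1", stacklevel=2)
        return FisherResult(p_value=1.0, method="degenerate")
    if counts.shape == (2, 2):
        return FisherResult(p_value=_fisher_2x2(counts), method="exact-2x2")
    if _enumeration_bound(counts.sum(axis=1), counts.sum(axis=0)) <= enumeration_budget:
        return FisherResult(p_value=_fisher_rxc_exact(counts), method="exact-enumeration")
    p, se = _fisher_monte_carlo(counts, mc_replicates, seed)
    return FisherResult(
        p_value=p, method="monte-carlo", mc_replicates=mc_replicates,
        mc_standard_error=se, seed=seed,
    )


# ---------------------------------------------------------------------------
# multiplicity, goodness of fit, flows


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_gof(
    observed: Sequence[int], expected_probs: Sequence[float]
) -> tuple[float, float]:
    """Pearson goodness-of-fit statistic against expected proportions.

    df = k - 1; returns (statistic, upper-tail p).
    """
    obs = np.asarray(observed, float)
    probs = np.asarray(expected_probs, float)
    if obs.shape != probs.shape:
        raise ValueError("observed and expected_probs must have the same length")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("expected_probs must sum to 1")
    expected = probs * obs.sum()
    if (expected == 0).any():
        raise ValueError("zero expected cell")
    stat = float(((obs - expected) ** 2 / expected).sum())
    from scipy import stats as sps

    p = float(sps.chi2.sf(stat, df=len(obs) - 1))
    return stat, p


def sankey_flows(table: ContingencyTable) -> list[dict]:
    """Flow list for a Sankey plot; zero-count flows omitted, margins conserved."""
    flows = []
    for i, src in enumerate(table.row_labels):
        for j, tgt in enumerate(table.col_labels):
            count = int(table.counts[i, j])
            if count > 0:
                flows.append({"source": src, "target": tgt, "count": count})
    return flows


# ---------------------------------------------------------------------------
# cohort-level scan


def pairwise_scan(
    cohort: Cohort,
    focal: str,
    features: Sequence[str],
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int | None = None,
    enumeration_budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> list[AssociationResult]:
    """Fisher-test the focal variable against each feature, BH-adjust, sort by p.

    Unknowns are dropped pairwise (per test), so each test uses the largest
    usable subsample; the per-test n is reported.  Features with fewer than
    two observed levels are skipped with a warning.
    """
    focal_schema = cohort.schema[focal] if focal in cohort.schema else None
    focal_values = cohort.feature_column(focal)
    results: list[tuple[str, ContingencyTable, FisherResult, int]] = []
    for feat in features:
        vs = cohort.schema[feat]
        values = cohort.feature_column(feat)
        pairs = [
            (f, v)
            for f, v in zip(focal_values, values)
            if (focal_schema.is_known(f) if focal_schema else f not in ("unknown", ""))
            and vs.is_known(v)
        ]
        if not pairs:
            warnings.warn(f"feature {feat!r}: no usable pairs; skipped", stacklevel=2)
            continue
        rows, cols = zip(*pairs)
        table = ContingencyTable.from_pairs(rows, cols, row_variable=focal, col_variable=feat)
        if len(table.row_labels) < 2 or len(table.col_labels) < 2:
            warnings.warn(f"feature {feat!r}: fewer than 2 observed levels; skipped", stacklevel=2)
            continue
        fr = fisher_exact(
            table, mc_replicates=mc_replicates, seed=seed, enumeration_budget=enumeration_budget
        )
        results.append((feat, table, fr, len(pairs)))

    adjusted = bh_adjust([fr.p_value for _, _, fr, _ in results]) if results else np.array([])
    out = [
        AssociationResult(
            feature=feat, table=table, p_raw=fr.p_value,
            p_adjusted=float(adj), n_used=n_used, test=fr,
        )
        for (feat, table, fr, n_used), adj in zip(results, adjusted)
    ]
    out.sort(key=lambda r: (r.p_raw, r.feature))
    return out
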