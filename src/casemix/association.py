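"""Cross-unit correlation of efficiency, risk and effectiveness indices.

Provider-level indices (the three EIs, RI and SI) are correlated pairwise
across basic care teams with the product-moment coefficient r; significance
uses the exact t transform ``t = r sqrt((n-2)/(1-r^2))`` with n-2 degrees of
freedom. A permutation p-value is available as an independent check of the
t-based one on small samples. A rank (Spearman) option is provided;
multiple-testing correction (Holm) is available but off by default, matching
the convention of reporting raw pairwise p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import format_pvalue, round_half_away
from .exceptions import CohortValidationError, UndefinedIndexError

__all__ = [
    "INDEX_COLUMNS", "pearson_r", "correlation_pvalue", "permutation_pvalue",
    "correlation_matrix", "render_correlation_table",
    "IndexAssociation", "AssociationResults",
]

#: default index columns correlated across units
INDEX_COLUMNS = ("visits_EI", "costs_EI", "episodes_EI", "RI", "SI")

_DISPLAY = {"visits_EI": "Visits EI", "costs_EI": "Cost EI",
            "episodes_EI": "Episodes EI", "RI": "Risk index", "SI": "Synthetic index"}


def _check_vectors(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise CohortValidationError(
            f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise CohortValidationError("correlation requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedIndexError("correlation undefined for a constant vector")


def pearson_r(x, y) -> float:
    """Product-moment correlation at full precision."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_vectors(x, y)
    return float(stats.pearsonr(x, y).statistic)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation ``r`` on ``n`` pairs (t transform).

    At ``|r| = 1`` the limit 0.0 is returned (the statistic is degenerate
    there; callers can detect the limit by the exact zero).
    """
    if n < 3:
        raise CohortValidationError("p-value requires n >= 3")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def permutation_pvalue(x, y, n_permutations: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the correlation of ``x`` and ``y``.

    Permutes ``y`` ``n_permutations`` times; p is the add-one estimator
    ``(1 + #{|r_perm| >= |r_obs|}) / (n_permutations + 1)``. Serves as the
    independent check of :func:`correlation_pvalue`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_vectors(x, y)
    r_obs = pearson_r(x, y)
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    perms = rng.permuted(np.tile(yc, (n_permutations, 1)), axis=1)
    r_perm = perms @ xc / x.shape[0]
    extreme = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
    return (1 + extreme) / (n_permutations + 1)


def correlation_matrix(
    unit_table: pd.DataFrame,
    columns=INDEX_COLUMNS,
    alpha: float = 0.05,
    method: str = "pearson",
    holm: bool = False,
) -> pd.DataFrame:
    """All pairwise correlations among the index columns of a per-unit table.

    Returns a tidy frame with one row per unordered pair: ``var1, var2, r,
    p_value, n, significant``. ``significant`` is ``p < alpha`` (strict).
    ``method='spearman'`` correlates ranks; ``holm=True`` applies the Holm
    step-down adjustment before the significance call.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    missing = [c for c in columns if c not in unit_table.columns]
    if missing:
        raise CohortValidationError(f"missing index columns: {missing}")
    data = unit_table[list(columns)].astype(float)
    if method == "spearman":
        data = data.rank()
    n = len(data)
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r = pearson_r(data[a], data[b])
            p = correlation_pvalue(r, n)
            rows.append({"var1": a, "var2": b, "r": r, "p_value": p, "n": n})
    out = pd.DataFrame(rows)
    if holm:
        out["p_adjusted"] = _holm(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def render_correlation_table(results: pd.DataFrame, digits: int = 2) -> str:
    """Triangular ``r (p)`` layout: rows Visits EI / Risk index / Synthetic
    index against columns Cost EI / Episodes EI / Risk index."""
    lookup = {}
    for _, row in results.iterrows():
        lookup[(row["var1"], row["var2"])] = (row["r"], row["p_value"])
        lookup[(row["var2"], row["var1"])] = (row["r"], row["p_value"])
    row_vars = ["visits_EI", "RI", "SI"]
    col_vars = ["costs_EI", "episodes_EI", "RI"]
    width = 18
    lines = ["".ljust(width) + "".join(_DISPLAY[c].ljust(width) for c in col_vars)]
    for rv in row_vars:
        cells = []
        for cv in col_vars:
            if rv == cv or (rv, cv) not in lookup:
                cells.append("".ljust(width))
            else:
                r, p = lookup[(rv, cv)]
                cells.append(
                    f"{round_half_away(r, digits):.{digits}f} ({format_pvalue(p)})".ljust(width))
        lines.append(_DISPLAY[rv].ljust(width) + "".join(cells))
    return "\n".join(lines)


class IndexAssociation:
    """Association model over a per-unit index table.

    Parameters
    ----------
    unit_table : DataFrame
        One row per unit with the five index columns (three EIs, RI, SI).
    alpha : float
        Significance level (strict ``p < alpha``).
    method : {'pearson', 'spearman'}
    holm : bool
        Apply Holm multiple-testing adjustment (off by default).
    """

    def __init__(self, unit_table, columns=INDEX_COLUMNS, alpha=0.05,
                 method="pearson", holm=False):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.unit_table = unit_table
        self.columns = tuple(columns)
        self.alpha = alpha
        self.method = method
        self.holm = holm

    def fit(self) -> "AssociationResults":
        corr = correlation_matrix(self.unit_table, self.columns,
                                  alpha=self.alpha, method=self.method, holm=self.holm)
        return AssociationResults(model=self, correlations=corr)


@dataclass
class AssociationResults:
    model: IndexAssociation
    correlations: pd.DataFrame

    def matrix(self) -> pd.DataFrame:
        """Symmetric r matrix with unit diagonal."""
        cols = list(self.model.columns)
        m = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        for _, row in self.correlations.iterrows():
            m.loc[row["var1"], row["var2"]] = row["r"]
            m.loc[row["var2"], row["var1"]] = row["r"]
        return m

    def summary(self) -> str:
        n = int(self.correlations["n"].iloc[0])
        head = (f"Pairwise {self.model.method} correlations over {n} units "
                f"(alpha={self.model.alpha}, "
                f"{'Holm-adjusted' if self.model.holm else 'raw p-values'})")
        return head + "\n\n" + render_correlation_table(self.correlations)

    def plot_scatter_matrix(self, path=None):
        """Scatter matrix of the index columns (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt  # noqa: F401
        from pandas.plotting import scatter_matrix
        axes = scatter_matrix(self.model.unit_table[list(self.model.columns)],
                              figsize=(8, 8), diagonal="hist")
        fig = axes[0, 0].get_figure()
        if path is not None:
            fig.savefig(path, dpi=120)
        return fig
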