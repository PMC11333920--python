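"""Per-genus environmental linear models with best-subset selection.

For each genus (and leaf compartment) the relative abundance is regressed on
the z-scored environmental factors.  The factor subset is chosen by
exhaustive search over all non-empty subsets, minimising the leave-one-out
prediction error MSEP = PRESS/n (computed in closed form from leverages).
Each selected factor is then tested by dropping it from the model with a
likelihood-ratio chi-square statistic, and p-values are pooled across all
genus x factor pairs for Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, TableError, aggregate_to_genus

__all__ = [
    "prepare_genus_table",
    "drop_collinear",
    "best_subset",
    "fit_and_test",
    "fdr_adjust",
    "top_shared_genera",
    "GenusEnvironmentModel",
    "GenusEnvironmentResults",
]


def prepare_genus_table(counts: CountTable, min_reads: int = 50) -> pd.DataFrame:
    """Genus x sample relative-abundance table with rare genera removed.

    OTUs are aggregated to genus, genera totalling fewer than ``min_reads``
    reads are excluded, and the remaining counts are column-normalised.
    """
    genus_counts = aggregate_to_genus(counts)
    totals = genus_counts.sum(axis=1)
    kept = genus_counts.loc[totals >= min_reads]
    if kept.empty:
        raise TableError(f"no genus reaches {min_reads} total reads")
    col = kept.sum(axis=0)
    nonzero = col.index[col > 0]
    return kept[nonzero] / kept[nonzero].sum(axis=0)


def drop_collinear(env: pd.DataFrame, r_max: float = 0.95):
    """Greedily remove factors until no pair correlates above ``|r_max|``.

    While any pair exceeds the threshold, the member with the higher mean
    absolute correlation to all other factors is dropped.  Returns the
    reduced frame and a report of (dropped, partner, r) tuples.
    """
    cols = list(env.columns)
    report = []
    while True:
        corr = env[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        if corr.iloc[i, j] <= r_max:
            break
        mean_abs = corr.mean(axis=0)
        a, b = corr.index[i], corr.columns[j]
        drop = a if mean_abs[a] >= mean_abs[b] else b
        keepmate = b if drop == a else a
        report.append((drop, keepmate, float(env[[a, b]].corr().iloc[0, 1])))
        cols.remove(drop)
        if len(cols) < 2:
            break
    return env[cols], report


def _press(y: np.ndarray, X: np.ndarray) -> float:
    """Leave-one-out PRESS for an OLS fit with intercept, via leverages."""
    Z = np.column_stack([np.ones(len(y)), X])
    Q, R = np.linalg.qr(Z)
    if np.abs(np.diag(R)).min() < 1e-10 * max(1.0, np.abs(R).max()):
        return np.inf  # rank-deficient subset: disqualify
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - Z @ beta
    h = np.einsum("ij,ij->i", Q, Q)
    denom = 1.0 - h
    if (denom <= 1e-10).any():
        return np.inf  # a leverage-one point makes LOO undefined
    e_loo = resid / denom
    return float(e_loo @ e_loo)


def best_subset(y: pd.Series | np.ndarray, X: pd.DataFrame, max_size: int | None = None):
    """Exhaustive best-subset selection by minimum MSEP (= PRESS/n).

    All non-empty factor subsets (optionally up to ``max_size``) are fitted;
    ties in MSEP are broken toward the smaller subset, then lexicographic
    factor order.  Returns ``(selected_factors, msep)``.
    """
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    limit = p if max_size is None else min(max_size, p)
    if n <= limit + 2:
        raise ValueError(f"need n > max subset size + 2 (n={n}, p={limit})")
    Xv = X.to_numpy(dtype=float)
    if limit == p and np.linalg.matrix_rank(
        np.column_stack([np.ones(n), Xv])
    ) < min(n, p + 1):
        # with a capped subset size, deficient subsets are simply skipped
        raise ValueError("design matrix is rank deficient; drop collinear factors")
    best_sel, best_msep = None, np.inf
    # size-ascending, lexicographic enumeration makes the tie-break implicit:
    # a later candidate must be strictly better to replace the incumbent
    for size in range(1, limit + 1):
        for combo in itertools.combinations(range(p), size):
            msep = _press(yv, Xv[:, combo]) / n
            if best_sel is None or msep < best_msep - 1e-12 * max(1.0, best_msep):
                best_sel, best_msep = combo, msep
    return [X.columns[i] for i in best_sel], float(best_msep)


def fit_and_test(y: pd.Series | np.ndarray, X_subset: pd.DataFrame):
    """Gaussian linear fit plus drop-one chi-square tests per factor.

    The drop-one statistic is the likelihood-ratio form
    ``n * ln(SSE_reduced / SSE_full)`` referred to chi-square with 1 df.
    Returns ``(coefficients, drop1_p)`` as factor-indexed Series (the
    intercept is reported under 'Intercept').
    """
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    Z = sm.add_constant(X_subset.to_numpy(dtype=float))
    fit = sm.OLS(yv, Z).fit()
    sse_full = float(fit.ssr)
    coefs = pd.Series(fit.params[1:], index=X_subset.columns)
    coefs["Intercept"] = fit.params[0]
    pvals = {}
    for k, factor in enumerate(X_subset.columns):
        keep = [c for c in X_subset.columns if c != factor]
        if keep:
            Zr = sm.add_constant(X_subset[keep].to_numpy(dtype=float))
        else:
            Zr = np.ones((n, 1))
        sse_red = float(sm.OLS(yv, Zr).fit().ssr)
        if sse_full <= 0:
            stat = np.inf if sse_red > 0 else 0.0
        else:
            stat = n * np.log(sse_red / sse_full)
        pvals[factor] = float(chi2.sf(max(stat, 0.0), df=1))
    return coefs, pd.Series(pvals)


def fdr_adjust(pvalues: pd.Series, alpha: float = 0.05) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw p)."""
    _, adj, _, _ = multipletests(pvalues.to_numpy(), alpha=alpha, method="fdr_bh")
    return pd.Series(adj, index=pvalues.index)


def top_shared_genera(
    results_epi: "GenusEnvironmentResults",
    results_endo: "GenusEnvironmentResults",
    k: int = 30,
) -> list[str]:
    """The k most environmentally responsive genera shared by compartments.

    Per genus per compartment the mean absolute coefficient over its selected
    factors scores responsiveness; genera present in both compartments are
    ranked by the mean of the two scores.
    """
    s_epi = results_epi.mean_abs_coefficient()
    s_endo = results_endo.mean_abs_coefficient()
    shared = s_epi.index.intersection(s_endo.index)
    score = (s_epi[shared] + s_endo[shared]) / 2.0
    if k > len(shared):
        warnings.warn(
            f"only {len(shared)} genera shared between compartments (k={k})",
            RuntimeWarning,
            stacklevel=2,
        )
    return score.sort_values(ascending=False).index[:k].tolist()


@dataclass
class GenusEnvironmentResults:
    """Fitted per-genus environmental models for one compartment.

    ``table`` is long format: genus, compartment, factor, coefficient, raw
    drop-one p, FDR-adjusted p and a selected flag; ``msep`` maps genus to
    the selected model's estimated prediction error.
    """

    table: pd.DataFrame
    msep: pd.Series
    compartment: str | None = None

    def mean_abs_coefficient(self) -> pd.Series:
        sel = self.table[self.table["selected"]]
        return sel.groupby("genus")["coefficient"].apply(lambda c: c.abs().mean())

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["selected"] & (self.table["p_adj"] < alpha)]

    def summary(self) -> str:
        n_gen = self.table["genus"].nunique()
        n_sig = len(self.significant())
        head = (
            f"Genus ~ environment models ({self.compartment or 'all'}): "
            f"{n_gen} genera, {n_sig} significant genus x factor pairs "
            f"(FDR < 0.05)\n"
        )
        return head + self.table.head(20).to_string(index=False)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class GenusEnvironmentModel:
    """Best-subset environmental regression for every genus in a table.

    Parameters
    ----------
    genus_ra
        Genus x sample relative abundances (see :func:`prepare_genus_table`).
    env_aligned
        Sample x factor z-scored environmental values matched to the same
        samples.
    compartment
        Optional label carried into the results.

    Examples
    --------
    >>> model = GenusEnvironmentModel(genus_ra, env_by_sample, "epiphyte")
    >>> res = model.fit()
    >>> res.significant().head()  # doctest: +SKIP
    """

    def __init__(
        self,
        genus_ra: pd.DataFrame,
        env_aligned: pd.DataFrame,
        compartment: str | None = None,
        max_subset_size: int | None = None,
    ):
        samples = genus_ra.columns.intersection(env_aligned.index)
        if len(samples) == 0:
            raise ValueError("no overlap between genus table samples and environment rows")
        self.genus_ra = genus_ra[samples]
        self.env = env_aligned.loc[samples]
        self.compartment = compartment
        self.max_subset_size = max_subset_size

    def fit(self) -> GenusEnvironmentResults:
        rows = []
        mseps = {}
        for genus in self.genus_ra.index:
            y = self.genus_ra.loc[genus]
            selected, msep = best_subset(y, self.env, max_size=self.max_subset_size)
            coefs, pvals = fit_and_test(y, self.env[selected])
            mseps[genus] = msep
            for factor in self.env.columns:
                in_model = factor in selected
                rows.append(
                    {
                        "genus": genus,
                        "compartment": self.compartment,
                        "factor": factor,
                        "coefficient": coefs.get(factor, np.nan) if in_model else np.nan,
                        "p": pvals.get(factor, np.nan) if in_model else np.nan,
                        "selected": in_model,
                    }
                )
        table = pd.DataFrame(rows)
        sel = table["selected"] & table["p"].notna()
        table["p_adj"] = np.nan
        if sel.any():
            table.loc[sel, "p_adj"] = fdr_adjust(table.loc[sel, "p"]).to_numpy()
        return GenusEnvironmentResults(
            table, pd.Series(mseps, name="msep"), self.compartment
        )
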