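"""Alpha diversity, Bray-Curtis dissimilarity, and PERMANOVA.

The PERMANOVA here is the multi-term, sequential (Type-I) sum-of-squares
partitioning of a distance matrix (McArdle & Anderson), the same model the
``adonis2`` convention fits: terms are added in the order given, each term's
sum of squares is the increment in explained (Gower-centred) inner-product
trace, and p-values come from free permutation of sample labels with the
add-one rule, so a permutation p-value is never zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from skbio import DistanceMatrix

from .tables import EnvTable, log10p_transform, to_relative_abundance

__all__ = [
    "shannon",
    "bray_curtis",
    "Permanova",
    "PermanovaResults",
    "env_permanova_screen",
    "diversity_env_correlation",
]


def shannon(counts: pd.DataFrame) -> pd.Series:
    """Shannon's H per sample (natural log): H = -sum p_i ln p_i, p_i > 0.

    ``counts`` is taxa x samples; raw counts and relative abundances give
    identical H since only the per-sample proportions enter.
    """
    arr = np.asarray(counts, dtype=float)
    total = arr.sum(axis=0)
    if np.any(total == 0):
        raise ValueError("cannot compute Shannon H for empty samples")
    p = arr / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-plogp.sum(axis=0), index=counts.columns, name="shannon_h")


def bray_curtis(table: pd.DataFrame, transform: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples (columns of ``table``).

    With ``transform=True`` (the default analysis convention here) counts are
    first converted to relative abundance and log10(x+1)-transformed.
    """
    df = table
    if transform:
        df = log10p_transform(to_relative_abundance(df))
    d = pdist(df.to_numpy(dtype=float).T, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(c) for c in table.columns])


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


class DesignError(ValueError):
    """Raised when a model term is constant or confounded with earlier terms."""


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _encode_term(term: str, data: pd.DataFrame) -> np.ndarray:
    """Columns for one term: dummies for categoricals, value for numerics,
    products of parent encodings for ':'-interactions."""
    parts = term.split(":")
    blocks = []
    for v in parts:
        if v not in data.columns:
            raise DesignError(f"variable {v!r} not found in sample data")
        col = data[v]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            blocks.append(col.to_numpy(dtype=float)[:, None])
        else:
            levels = pd.unique(col)
            if len(levels) < 2:
                raise DesignError(f"factor {v!r} has fewer than 2 levels")
            blocks.append(
                np.column_stack([(col == lv).to_numpy(float) for lv in levels])
            )
    out = blocks[0]
    for b in blocks[1:]:
        out = (out[:, :, None] * b[:, None, :]).reshape(len(b), -1)
    return out


@dataclass
class PermanovaResults:
    """Sequential PERMANOVA partitioning of a distance matrix.

    ``table`` has one row per model term plus Residual and Total rows, with
    columns df, SumOfSqs, R2, F and ``Pr(>F)``; R2 values (terms + residual)
    sum to one.
    """

    table: pd.DataFrame
    n_permutations: int
    permutation_scheme: str

    def summary(self) -> str:
        header = (
            f"PERMANOVA (sequential SS, {self.n_permutations} "
            f"{self.permutation_scheme} permutations)\n"
        )
        return header + self.table.to_string(float_format=lambda x: f"{x:.6g}")

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def r2(self) -> pd.Series:
        return self.table["R2"].drop(["Residual", "Total"])

    @property
    def pvalues(self) -> pd.Series:
        return self.table["Pr(>F)"].drop(["Residual", "Total"])


class Permanova:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    distance_matrix
        ``skbio.DistanceMatrix`` or square ndarray/DataFrame of pairwise
        dissimilarities.
    data
        Sample data frame aligned to the distance matrix ids, holding the
        model variables (categorical or continuous).
    terms
        Ordered model terms; ``"a:b"`` denotes an interaction.  Order matters
        (Type-I sums of squares).

    Examples
    --------
    >>> model = Permanova(dm, metadata, ["compartment", "site", "season"])
    >>> res = model.fit(n_permutations=999, seed=0)
    >>> res.table  # doctest: +SKIP
    """

    def __init__(self, distance_matrix, data: pd.DataFrame, terms: list[str]):
        if isinstance(distance_matrix, DistanceMatrix):
            d = distance_matrix.data
            ids = list(distance_matrix.ids)
        else:
            d = np.asarray(
                distance_matrix.values
                if isinstance(distance_matrix, pd.DataFrame)
                else distance_matrix,
                dtype=float,
            )
            ids = (
                list(distance_matrix.index)
                if isinstance(distance_matrix, pd.DataFrame)
                else list(data.index)
            )
        if d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        missing = set(map(str, ids)) - set(map(str, data.index))
        if missing:
            raise ValueError(f"samples missing from data: {sorted(missing)[:5]}")
        self.d = d
        self.ids = ids
        self.data = data.loc[ids]
        if not terms:
            raise ValueError("at least one model term is required")
        self.terms = list(terms)

    @classmethod
    def from_dataframe(cls, distance_matrix, data, terms) -> "Permanova":
        return cls(distance_matrix, data, terms)

    # ------------------------------------------------------------------
    def _bases(self):
        """Orthonormal basis increments per term (sequential projection)."""
        n = self.d.shape[0]
        Q = np.ones((n, 1)) / math.sqrt(n)  # intercept
        bases, dfs = [], []
        for term in self.terms:
            X = _encode_term(term, self.data)
            resid = X - Q @ (Q.T @ X)
            qk, rk = np.linalg.qr(resid)
            keep = np.abs(np.diag(rk)) > 1e-8 * max(1.0, np.abs(rk).max())
            qk = qk[:, keep]
            if qk.shape[1] == 0:
                raise DesignError(
                    f"term {term!r} is confounded with earlier terms "
                    "(adds no rank to the design)"
                )
            bases.append(qk)
            dfs.append(qk.shape[1])
            Q = np.hstack([Q, qk])
        return bases, dfs

    def fit(
        self,
        n_permutations: int = 10_000,
        seed: int | None = None,
        exact: bool = False,
        strata: str | None = None,
    ) -> PermanovaResults:
        """Partition the distances and permute for p-values.

        ``exact=True`` enumerates all n! sample relabelings (n <= 8) and
        reports p as the fraction of relabelings with F >= observed (the
        identity included).  Otherwise p uses ``n_permutations`` random
        permutations with the add-one rule; ``strata`` names a column of the
        sample data within whose levels permutation is restricted (defaults
        to free permutation of all rows).
        """
        G = _gower_center(self.d)
        n = G.shape[0]
        bases, dfs = self._bases()
        ss_total = float(np.trace(G))
        ss_terms = np.array([float(np.einsum("im,ij,jm->", Q, G, Q)) for Q in bases])
        df_res = n - 1 - sum(dfs)
        if df_res <= 0:
            raise DesignError("model saturates the data (no residual df)")
        ss_res = ss_total - ss_terms.sum()
        f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

        Qall = np.hstack(bases)
        splits = np.cumsum(dfs)[:-1]

        dfs_arr = np.array(dfs, dtype=float)

        def f_for(idx_matrix: np.ndarray, chunk: int = 256) -> np.ndarray:
            """Term-wise pseudo-F for each permutation (rows of idx_matrix)."""
            out = np.empty((idx_matrix.shape[0], len(dfs)))
            for start in range(0, idx_matrix.shape[0], chunk):
                idx = idx_matrix[start : start + chunk]
                Qp = Qall[idx]  # (chunk, n, m)
                GQ = np.einsum("ij,pjm->pim", G, Qp)
                diag = np.einsum("pim,pim->pm", Qp, GQ)
                parts = np.add.reduceat(diag, np.r_[0, splits], axis=1)
                res = ss_total - parts.sum(axis=1, keepdims=True)
                out[start : start + chunk] = (parts / dfs_arr) / (res / df_res)
            return out

        if exact:
            if n > 8:
                raise ValueError("exact enumeration limited to n <= 8 samples")
            perms = np.array(list(itertools.permutations(range(n))))
            f_perm = f_for(perms)
            # identity is among the enumerated relabelings
            pvals = (f_perm >= f_obs - 1e-12).mean(axis=0)
            n_used, scheme = len(perms), "exact"
        else:
            rng = np.random.default_rng(seed)
            if strata is None:
                perms = np.array(
                    [rng.permutation(n) for _ in range(n_permutations)]
                )
                scheme = "free"
            else:
                if strata not in self.data.columns:
                    raise DesignError(f"strata column {strata!r} not found")
                blocks = [
                    np.flatnonzero(self.data[strata].to_numpy() == lv)
                    for lv in pd.unique(self.data[strata])
                ]
                perms = np.tile(np.arange(n), (n_permutations, 1))
                for block in blocks:
                    for row in perms:
                        row[block] = block[rng.permutation(len(block))]
                scheme = f"within-{strata}"
            f_perm = f_for(perms)
            exceed = (f_perm >= f_obs - 1e-12).sum(axis=0)
            pvals = (exceed + 1) / (n_permutations + 1)
            n_used = n_permutations

        rows = []
        for term, df, ss, f, p in zip(self.terms, dfs, ss_terms, f_obs, pvals):
            rows.append((term, df, ss, ss / ss_total, f, p))
        rows.append(("Residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan))
        rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["term", "df", "SumOfSqs", "R2", "F", "Pr(>F)"]
        ).set_index("term")
        return PermanovaResults(table, n_used, scheme)


def env_permanova_screen(
    distance_matrix,
    env_aligned: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """One single-factor PERMANOVA per environmental factor.

    ``env_aligned`` is samples x factors (continuous values matched to the
    distance-matrix samples); each factor is fitted alone as a one-df
    regression term.  Returns a tidy frame (factor, df, SumOfSqs, R2, F, p).
    """
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(env_aligned.columns))
    for factor, child in zip(env_aligned.columns, seeds):
        col = env_aligned[[factor]]
        if col[factor].nunique() < 2:
            raise DesignError(f"environmental factor {factor!r} is constant")
        res = Permanova(distance_matrix, col, [factor]).fit(
            n_permutations=n_permutations,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        r = res.table.loc[factor]
        rows.append(
            (factor, int(r["df"]), r["SumOfSqs"], r["R2"], r["F"], r["Pr(>F)"])
        )
    return pd.DataFrame(
        rows, columns=["factor", "df", "SumOfSqs", "R2", "F", "p"]
    ).set_index("factor")


def diversity_env_correlation(
    h: pd.Series, env_aligned: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of per-sample alpha diversity with each factor."""
    rows = []
    for factor in env_aligned.columns:
        rho, p = spearmanr(h.to_numpy(), env_aligned[factor].to_numpy())
        rows.append((factor, rho, p))
    return pd.DataFrame(rows, columns=["factor", "rho", "p"]).set_index("factor")
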