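"""SparCC: correlation inference for sparse compositional count data.

Sequencing counts carry only relative information, so naive correlations of
fractions are distorted by the closure constraint.  SparCC works on
Aitchison log-ratio variances ``t_ij = Var(ln x_i/x_j)``, which are invariant
to per-sample scaling, and inverts them for the latent ("basis") variances
``omega_i`` under a sparsity assumption (most pairs uncorrelated):

    t_ij = omega_i + omega_j - 2 rho_ij sqrt(omega_i omega_j)

With sum_j rho_ij sqrt(omega_i omega_j) ~ 0, row sums of t satisfy the
linear system ``[(D-2) I + J] omega = t 1`` (J the all-ones matrix).  Pairs
whose estimated |rho| exceeds a threshold are iteratively excluded from the
system (they violate sparsity), and the whole estimate is repeated over
several Dirichlet resamplings of the fractions, taking the elementwise
median.  Pseudo p-values come from bootstrap datasets in which each OTU's
counts are resampled independently across samples, destroying inter-OTU
association while preserving marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "estimate_fractions",
    "log_ratio_variance",
    "solve_basis_variances",
    "correlation_from_basis",
    "sparcc",
    "bootstrap_pvalues",
    "SparCC",
    "SparCCResults",
]

OMEGA_FLOOR = 1e-12


class SparccError(ValueError):
    pass


def _as_matrix(counts) -> tuple[np.ndarray, list]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index)
    arr = np.asarray(counts, dtype=float)
    return arr, [f"Otu{i + 1}" for i in range(arr.shape[0])]


def estimate_fractions(
    counts: np.ndarray, mode: str = "posterior_mean", rng=None
) -> np.ndarray:
    """Per-sample fraction estimates from counts (OTU x sample).

    ``posterior_mean``: f_ij = (c_ij + 1)/(N_j + D), the mean of the
    Dirichlet posterior under a uniform prior.  ``dirichlet_draw``: one draw
    from Dirichlet(counts_column + 1) per sample.
    """
    c = np.asarray(counts, dtype=float)
    D = c.shape[0]
    if mode == "posterior_mean":
        return (c + 1.0) / (c.sum(axis=0, keepdims=True) + D)
    if mode == "dirichlet_draw":
        if rng is None:
            rng = np.random.default_rng()
        g = rng.standard_gamma(c + 1.0)
        return g / g.sum(axis=0, keepdims=True)
    raise ValueError(f"unknown fraction mode {mode!r}")


def log_ratio_variance(fractions: np.ndarray) -> np.ndarray:
    """Variation matrix t_ij = Var over samples of ln(f_i/f_j).

    Computed from the covariance of log fractions:
    t_ij = V_i + V_j - 2 C_ij (invariant to per-sample rescaling, which only
    shifts every log fraction within a sample by a constant).
    """
    logf = np.log(np.asarray(fractions, dtype=float))
    if logf.shape[1] < 2:
        raise SparccError("need at least 2 samples for log-ratio variances")
    C = np.cov(logf, ddof=1)
    v = np.diag(C)
    t = v[:, None] + v[None, :] - 2.0 * C
    np.fill_diagonal(t, 0.0)
    return np.clip(t, 0.0, None)


def solve_basis_variances(
    t: np.ndarray, excluded_pairs: list[tuple[int, int]] = ()
) -> np.ndarray:
    """Solve the sparsity-approximation linear system for basis variances.

    With no exclusions the system is ``[(D-2) I + J] omega = rowsum(t)``.
    Each excluded pair (i, j) removes t_ij from both row sums and decrements
    the matching diagonal and off-diagonal coefficients.  Variances below
    1e-12 are clamped (with a warning) rather than propagated as negatives.
    """
    t = np.asarray(t, dtype=float)
    D = t.shape[0]
    if D < 4:
        raise SparccError(f"basis variances are underdetermined for D={D} < 4")
    M = np.ones((D, D)) + (D - 2) * np.eye(D)
    rhs = t.sum(axis=1)
    n_excl = np.zeros(D, dtype=int)
    for i, j in excluded_pairs:
        rhs[i] -= t[i, j]
        rhs[j] -= t[i, j]
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        n_excl[i] += 1
        n_excl[j] += 1
    over = np.flatnonzero(n_excl >= D - 1)
    if over.size:
        raise SparccError(
            f"all partners excluded for OTU indices {over.tolist()}; "
            "system is singular"
        )
    try:
        omega = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as err:
        raise SparccError(
            f"singular reduced system (over-excluded OTUs: "
            f"{np.flatnonzero(n_excl >= D - 3).tolist()})"
        ) from err
    if (omega < OMEGA_FLOOR).any():
        warnings.warn(
            f"{int((omega < OMEGA_FLOOR).sum())} basis variances clamped to "
            f"{OMEGA_FLOOR}",
            RuntimeWarning,
            stacklevel=2,
        )
        omega = np.clip(omega, OMEGA_FLOOR, None)
    return omega


def correlation_from_basis(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """rho_ij = (omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j)),
    clipped to [-1, 1] with a unit diagonal."""
    om = np.asarray(omega, dtype=float)
    denom = 2.0 * np.sqrt(np.outer(om, om))
    rho = (om[:, None] + om[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_round(
    t: np.ndarray, exclusion_threshold: float, max_exclusions: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One estimation round: iteratively exclude the strongest pair."""
    D = t.shape[0]
    excluded: list[tuple[int, int]] = []
    n_excl = np.zeros(D, dtype=int)
    mask = np.zeros((D, D), dtype=bool)  # True = pair unavailable
    np.fill_diagonal(mask, True)
    rho = None
    for _ in range(max_exclusions + 1):
        omega = solve_basis_variances(t, excluded)
        rho = correlation_from_basis(t, omega)
        if len(excluded) >= max_exclusions:
            break
        cand = np.abs(np.where(mask, 0.0, rho))
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        # keep every OTU with >= 3 usable partners so the system stays regular
        if n_excl[i] >= D - 4 or n_excl[j] >= D - 4:
            mask[i, j] = mask[j, i] = True
            continue
        excluded.append((int(i), int(j)))
        n_excl[i] += 1
        n_excl[j] += 1
        mask[i, j] = mask[j, i] = True
    return rho, excluded


def sparcc(
    counts,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    n_outer: int = 50,
    seed: int | None = None,
    mode: str = "dirichlet_draw",
):
    """Estimate the basis correlation matrix from compositional counts.

    Each outer round draws fresh fractions (Dirichlet resampling of the
    counts), computes log-ratio variances, and runs the exclusion iteration;
    the returned ``rho`` is the elementwise median across rounds.
    Deterministic for a fixed seed.

    Returns ``(rho, excluded_pairs)`` where ``excluded_pairs`` is the union
    of pair exclusions over rounds (as index tuples).
    """
    c, _ = _as_matrix(counts)
    D, n = c.shape
    if D < 4:
        raise SparccError(f"SparCC needs at least 4 OTUs (got {D})")
    if n < 2:
        raise SparccError(f"SparCC needs at least 2 samples (got {n})")
    zero_rows = np.flatnonzero(c.sum(axis=1) == 0)
    if zero_rows.size:
        raise SparccError(
            f"all-zero OTU rows {zero_rows.tolist()}: apply the prevalence "
            "filter before correlation estimation"
        )
    rng = np.random.default_rng(seed)
    rhos = np.empty((n_outer, D, D))
    excluded_union: set[tuple[int, int]] = set()
    for r in range(n_outer):
        f = estimate_fractions(c, mode=mode, rng=rng)
        t = log_ratio_variance(f)
        rho_r, excl = _sparcc_round(t, exclusion_threshold, max_exclusions)
        rhos[r] = rho_r
        excluded_union.update(excl)
    rho = np.median(rhos, axis=0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho, sorted(excluded_union)


def _null_dataset(c: np.ndarray, rng, scheme: str) -> np.ndarray:
    n = c.shape[1]
    if scheme == "resample":
        idx = rng.integers(0, n, size=(c.shape[0], n))
        return np.take_along_axis(c, idx, axis=1)
    if scheme == "permute":
        return np.array([row[rng.permutation(n)] for row in c])
    raise ValueError(f"unknown null scheme {scheme!r}")


def bootstrap_pvalues(
    counts,
    rho_obs: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    n_outer_boot: int = 5,
    null: str = "resample",
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
) -> np.ndarray:
    """Two-sided bootstrap pseudo p-values for SparCC correlations.

    Each bootstrap dataset resamples the per-sample counts of every OTU row
    independently (with replacement), breaking inter-OTU association while
    preserving marginal distributions.  SparCC is re-run on each dataset
    (with ``n_outer_boot`` outer rounds for tractability) and

        p_ij = (#{|rho_boot| >= |rho_obs|} + 1) / (n_boot + 1),

    so the smallest attainable p is 1/(n_boot + 1): with 1000 bootstraps
    that floor (~9.99e-4) makes a p <= .001 edge filter exactly attainable.
    """
    if n_boot < 1:
        raise SparccError("n_boot must be >= 1")
    c, _ = _as_matrix(counts)
    rho_obs = np.asarray(rho_obs, dtype=float)
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(rho_obs)
    exceed = np.zeros_like(abs_obs)
    for _ in range(n_boot):
        boot = _null_dataset(c, rng, null)
        rho_b, _ = sparcc(
            boot,
            exclusion_threshold=exclusion_threshold,
            max_exclusions=max_exclusions,
            n_outer=n_outer_boot,
            seed=int(rng.integers(0, 2**31)),
        )
        exceed += np.abs(rho_b) >= abs_obs - 1e-12
    p = (exceed + 1.0) / (n_boot + 1.0)
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 1.0)
    return p


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


@dataclass
class SparCCResults:
    """Estimated basis correlations and bootstrap pseudo p-values.

    ``rho`` and ``pvalues`` are square OTU x OTU DataFrames (pvalues is None
    when fitted without bootstraps); ``excluded_pairs`` lists OTU id pairs
    removed from the basis-variance system during estimation.
    """

    rho: pd.DataFrame
    pvalues: pd.DataFrame | None
    excluded_pairs: list[tuple[str, str]]
    n_bootstraps: int
    seed: int | None

    def __post_init__(self) -> None:
        r = self.rho.to_numpy()
        assert np.allclose(r, r.T, atol=1e-12), "rho must be symmetric"
        assert np.allclose(np.diag(r), 1.0), "rho diagonal must be 1"
        assert np.abs(r).max() <= 1.0 + 1e-12, "|rho| must be <= 1"

    @property
    def otu_ids(self) -> list[str]:
        return list(self.rho.index)

    def significant_pairs(self, p_max: float = 0.001) -> pd.DataFrame:
        """Long table of OTU pairs with p <= p_max and |rho| > 0."""
        if self.pvalues is None:
            raise ValueError("fit with n_bootstraps > 0 to obtain p-values")
        ids = self.otu_ids
        rows = []
        r, p = self.rho.to_numpy(), self.pvalues.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if p[i, j] <= p_max and abs(r[i, j]) > 0:
                    rows.append((ids[i], ids[j], r[i, j], p[i, j]))
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p"])

    def summary(self) -> str:
        r = self.rho.to_numpy()
        off = r[np.triu_indices_from(r, k=1)]
        lines = [
            f"SparCC correlations over {len(self.otu_ids)} OTUs",
            f"  bootstraps: {self.n_bootstraps}",
            f"  mean |rho| (off-diagonal): {np.abs(off).mean():.4f}",
            f"  excluded pairs: {len(self.excluded_pairs)}",
        ]
        if self.pvalues is not None:
            n_sig = len(self.significant_pairs())
            lines.append(f"  pairs with p <= 0.001: {n_sig}")
        return "\n".join(lines)

    def to_tsv(self, prefix: str) -> None:
        """Write ``<prefix>.rho.tsv`` (and ``.pval.tsv``) square matrices."""
        self.rho.to_csv(f"{prefix}.rho.tsv", sep="\t")
        if self.pvalues is not None:
            self.pvalues.to_csv(f"{prefix}.pval.tsv", sep="\t")


class SparCC:
    """SparCC model for one (time point, compartment) stratum.

    Parameters
    ----------
    counts
        OTU x sample DataFrame (or array) of raw counts after the prevalence
        filter.
    exclusion_threshold, max_exclusions, n_outer
        Estimation defaults mirror the published SparCC/FastSpar defaults
        (0.1, 10 and 50).

    Examples
    --------
    >>> res = SparCC(counts).fit(n_bootstraps=1000, seed=1)
    >>> net_edges = res.significant_pairs(p_max=0.001)
    """

    def __init__(
        self,
        counts,
        exclusion_threshold: float = 0.1,
        max_exclusions: int = 10,
        n_outer: int = 50,
    ):
        arr, ids = _as_matrix(counts)
        self.counts = arr
        self.otu_ids = [str(i) for i in ids]
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusions = max_exclusions
        self.n_outer = n_outer

    def fit(
        self,
        n_bootstraps: int = 0,
        seed: int | None = None,
        n_outer_boot: int = 5,
        null: str = "resample",
        mode: str = "dirichlet_draw",
    ) -> SparCCResults:
        ss = np.random.SeedSequence(seed)
        est_seed, boot_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        rho, excluded = sparcc(
            self.counts,
            exclusion_threshold=self.exclusion_threshold,
            max_exclusions=self.max_exclusions,
            n_outer=self.n_outer,
            seed=est_seed,
            mode=mode,
        )
        rho_df = pd.DataFrame(rho, index=self.otu_ids, columns=self.otu_ids)
        pval_df = None
        if n_bootstraps > 0:
            p = bootstrap_pvalues(
                self.counts,
                rho,
                n_boot=n_bootstraps,
                seed=boot_seed,
                n_outer_boot=n_outer_boot,
                null=null,
                exclusion_threshold=self.exclusion_threshold,
                max_exclusions=self.max_exclusions,
            )
            pval_df = pd.DataFrame(p, index=self.otu_ids, columns=self.otu_ids)
        pairs = [(self.otu_ids[i], self.otu_ids[j]) for i, j in excluded]
        return SparCCResults(rho_df, pval_df, pairs, n_bootstraps, seed)
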