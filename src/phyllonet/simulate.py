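"""Synthetic multikingdom leaf-microbiome data with planted ground truth.

The generator emulates the study design the package analyses: six sites
sampled in fall and spring over five years (11 time points), each plant
yielding an epiphytic (leaf surface) and an endophytic (leaf interior)
sample, with bacterial, fungal and non-fungal-eukaryote OTUs pooled into one
table.  Counts are compositional: latent *basis* abundances are drawn
multivariate log-normal with a known correlation matrix, converted to
fractions, and observed through a multinomial read-sampling step.  Because
the basis correlations, environmental effects and the compartment richness
gap are planted, every downstream estimator can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .tables import CountTable, EnvTable, TERRACLIMATE_FACTORS

__all__ = [
    "SimTruth",
    "SimDesign",
    "simulate_counts",
    "simulate_env",
    "simulate_genus_env_link",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one simulated community.

    Attributes
    ----------
    basis_correlation
        D x D symmetric positive-semidefinite matrix with unit diagonal:
        the correlation of log basis abundances.
    basis_log_mean, basis_log_sd
        Mean and standard deviation of each OTU's log basis abundance.
    env_effects
        Genus x factor coefficient matrix of planted environmental effects
        (used by :func:`simulate_genus_env_link`).
    compartment_richness_ratio
        Target ratio of epiphyte to endophyte realised richness; endophyte
        samples are drawn from a basis with a fixed random subset of OTUs
        masked to zero so the ratio is approximately met.
    seed
        Seed for all randomness attributable to this truth object.
    """

    basis_correlation: np.ndarray
    basis_log_mean: np.ndarray
    basis_log_sd: np.ndarray
    env_effects: pd.DataFrame | None = None
    compartment_richness_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.basis_correlation, dtype=float)
        object.__setattr__(self, "basis_correlation", R)
        object.__setattr__(
            self, "basis_log_mean", np.asarray(self.basis_log_mean, dtype=float)
        )
        object.__setattr__(
            self, "basis_log_sd", np.asarray(self.basis_log_sd, dtype=float)
        )
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise SimulationError("basis_correlation must be square")
        if not np.allclose(R, R.T, atol=1e-12):
            raise SimulationError("basis_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise SimulationError("basis_correlation diagonal must be exactly 1")
        lo = float(np.linalg.eigvalsh(R).min())
        if lo < -1e-10:
            raise SimulationError(
                f"basis_correlation is not positive semidefinite "
                f"(smallest eigenvalue {lo:.3e})"
            )
        if (self.basis_log_sd <= 0).any():
            raise SimulationError("basis_log_sd must be positive")
        if self.env_effects is not None and not np.isfinite(
            self.env_effects.to_numpy()
        ).all():
            raise SimulationError("env_effects must be finite")
        if self.compartment_richness_ratio <= 0:
            raise SimulationError("compartment_richness_ratio must be positive")

    @property
    def n_otus(self) -> int:
        return self.basis_correlation.shape[0]

    @classmethod
    def with_planted_pairs(
        cls,
        n_otus: int,
        planted: dict[tuple[int, int], float] | None = None,
        log_sd: float = 1.0,
        compartment_richness_ratio: float = 2.0,
        seed: int = 0,
    ) -> "SimTruth":
        """Identity correlation with a few planted pairwise correlations."""
        R = np.eye(n_otus)
        for (i, j), rho in (planted or {}).items():
            R[i, j] = R[j, i] = rho
        lo = float(np.linalg.eigvalsh(R).min())
        if lo < -1e-10:
            raise SimulationError(
                f"planted correlations make the matrix non-PSD "
                f"(smallest eigenvalue {lo:.3e})"
            )
        return cls(
            basis_correlation=R,
            basis_log_mean=np.zeros(n_otus),
            basis_log_sd=np.full(n_otus, log_sd),
            compartment_richness_ratio=compartment_richness_ratio,
            seed=seed,
        )


@dataclass(frozen=True)
class SimDesign:
    """Sampling design: sites x time points x replicates x compartments.

    Defaults mirror the study layout: 6 sites, 11 alternating spring/fall
    time points starting spring 2014, and per-sample sequencing depths drawn
    uniformly from 10^4..10^5 reads.
    """

    n_sites: int = 6
    n_timepoints: int = 11
    samples_per_site_per_timepoint: int = 3
    sequencing_depth_range: tuple[int, int] = (10_000, 100_000)
    n_otus: dict = field(
        default_factory=lambda: {"bacteria": 30, "fungi": 12, "nfeuk": 8}
    )
    start_year: int = 2014
    season_months: dict = field(default_factory=lambda: {"spring": 3, "fall": 11})

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_timepoints, self.samples_per_site_per_timepoint) < 1:
            raise SimulationError("design counts must be positive")
        lo, hi = self.sequencing_depth_range
        if lo < 1 or hi < lo:
            raise SimulationError("sequencing depth range must satisfy 1 <= min <= max")
        if any(v < 1 for v in self.n_otus.values()):
            raise SimulationError("n_otus per kingdom must be positive")

    @property
    def total_otus(self) -> int:
        return sum(self.n_otus.values())

    def season_of(self, timepoint: int) -> str:
        # spring 2014, fall 2014, spring 2015, ... (springs at even indices)
        return "spring" if timepoint % 2 == 0 else "fall"

    def year_of(self, timepoint: int) -> int:
        return self.start_year + (timepoint + 1) // 2

    def month_of(self, timepoint: int) -> int:
        return self.season_months[self.season_of(timepoint)]

    def sites(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]

    def timepoint_key(self) -> pd.DataFrame:
        """One row per time point: timepoint, season, year, month."""
        return pd.DataFrame(
            {
                "timepoint": range(self.n_timepoints),
                "season": [self.season_of(t) for t in range(self.n_timepoints)],
                "year": [self.year_of(t) for t in range(self.n_timepoints)],
                "month": [self.month_of(t) for t in range(self.n_timepoints)],
            }
        )


def _kingdom_labels(design: SimDesign) -> list[str]:
    labels: list[str] = []
    for kingdom, n in design.n_otus.items():
        labels.extend([kingdom] * n)
    return labels


def simulate_counts(truth: SimTruth, design: SimDesign):
    """Draw a compositional multikingdom count table with planted structure.

    Per sample, log basis abundances are multivariate normal with the
    planted correlation, basis abundances their exponentials, fractions the
    basis normalised to one, and counts a multinomial draw at that sample's
    sequencing depth.  Endophyte samples use a basis in which a fixed random
    OTU subset is zeroed, so the epiphyte/endophyte realised-richness ratio
    approximates ``truth.compartment_richness_ratio``.

    Returns ``(CountTable, SimTruth)`` — the truth object is echoed so the
    planted structure travels with the data.
    """
    D = truth.n_otus
    if D != design.total_otus:
        raise SimulationError(
            f"truth has {D} OTUs but design specifies {design.total_otus}"
        )
    rng = np.random.default_rng(truth.seed)

    # eigendecomposition handles PSD-but-singular planted matrices
    w, V = np.linalg.eigh(truth.basis_correlation)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)

    # fixed endophyte mask: keep ~D/ratio OTUs, spread across kingdoms
    n_keep = max(4, int(round(D / truth.compartment_richness_ratio)))
    endo_kept = np.sort(rng.choice(D, size=min(n_keep, D), replace=False))
    endo_mask = np.zeros(D, dtype=bool)
    endo_mask[endo_kept] = True

    otu_ids = [f"Otu{i + 1:04d}" for i in range(D)]
    kingdoms = _kingdom_labels(design)
    lo, hi = design.sequencing_depth_range

    cols, meta_rows, names = [], [], []
    for t in range(design.n_timepoints):
        for site in design.sites():
            for rep in range(design.samples_per_site_per_timepoint):
                z = L @ rng.standard_normal(D)
                log_basis = truth.basis_log_mean + truth.basis_log_sd * z
                basis = np.exp(log_basis)
                for compartment in ("epiphyte", "endophyte"):
                    b = basis if compartment == "epiphyte" else basis * endo_mask
                    fractions = b / b.sum()
                    depth = int(rng.integers(lo, hi + 1))
                    cols.append(rng.multinomial(depth, fractions))
                    names.append(f"t{t:02d}.{site}.r{rep + 1}.{compartment[:3]}")
                    meta_rows.append(
                        {
                            "compartment": compartment,
                            "site": site,
                            "season": design.season_of(t),
                            "year": design.year_of(t),
                            "timepoint": t,
                        }
                    )
    counts = pd.DataFrame(
        np.column_stack(cols), index=otu_ids, columns=names
    )
    metadata = pd.DataFrame(meta_rows, index=names)
    taxonomy = pd.Series(
        [
            f"{k.capitalize()};Phylum{i % 5 + 1};Class{i % 7 + 1};Order{i % 9 + 1};"
            f"Family{i % 11 + 1};Genus{i + 1:03d}"
            for i, k in enumerate(kingdoms)
        ],
        index=otu_ids,
    )
    table = CountTable(
        counts, metadata, taxonomy=taxonomy, kingdom=pd.Series(kingdoms, index=otu_ids)
    )
    return table, truth


def simulate_env(
    design: SimDesign,
    seasonal_amplitudes: dict | float = 1.0,
    site_offsets: pd.DataFrame | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> EnvTable:
    """Site- and season-structured environmental factors.

    Each factor value is ``site offset + seasonal sinusoid + Gaussian
    noise``; the sinusoid has a one-year period with a factor-specific phase,
    so fall and spring means differ whenever the amplitude is positive.
    Deterministic for a fixed seed.
    """
    if design.n_timepoints < 2:
        raise SimulationError("need at least 2 time points to simulate environment")
    rng = np.random.default_rng(seed)
    factors = list(TERRACLIMATE_FACTORS)
    if isinstance(seasonal_amplitudes, dict):
        amps = np.array([seasonal_amplitudes.get(f, 0.0) for f in factors])
    else:
        amps = np.full(len(factors), float(seasonal_amplitudes))
    sites = design.sites()
    if site_offsets is None:
        site_offsets = pd.DataFrame(
            rng.normal(0.0, 0.5, size=(len(sites), len(factors))),
            index=sites,
            columns=factors,
        )
    phases = 2.0 * np.pi * np.arange(len(factors)) / len(factors)

    key = design.timepoint_key().drop_duplicates(subset=["year", "month"])
    rows, idx = [], []
    for _, tp in key.iterrows():
        season_term = amps * np.sin(
            2.0 * np.pi * tp["month"] / 12.0 + phases + 0.25
        )
        for site in sites:
            noise = rng.normal(0.0, noise_sd, size=len(factors))
            rows.append(site_offsets.loc[site].to_numpy() + season_term + noise)
            idx.append((site, int(tp["year"]), int(tp["month"])))
    values = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(idx, names=["site", "year", "month"]),
        columns=factors,
    )
    return EnvTable(values, z_transformed=False)


def simulate_genus_env_link(
    env: EnvTable,
    env_effects: pd.DataFrame,
    intercepts: pd.Series | float = -3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genus relative abundances linked to environmental factors.

    For genus g and environment row x:
    ``RA_g = logistic(intercept_g + x . beta_g + noise)``.  Columns whose
    total exceeds 1 are rescaled to sum to 1, so per-sample totals are <= 1.
    Requires a z-transformed environment so planted coefficients are on the
    standardised scale the downstream models fit on.
    """
    if not env.z_transformed:
        raise SimulationError("environment must be z-transformed before linking")
    unknown = set(env_effects.columns) - set(env.factors)
    if unknown:
        raise SimulationError(
            f"effect columns not in environmental factors: {sorted(unknown)}"
        )
    rng = np.random.default_rng(seed)
    X = env.values[env_effects.columns].to_numpy()  # rows x factors
    B = env_effects.to_numpy()  # genera x factors
    if isinstance(intercepts, pd.Series):
        a = intercepts.reindex(env_effects.index).to_numpy()
    else:
        a = np.full(len(env_effects), float(intercepts))
    eta = a[:, None] + B @ X.T
    if noise_sd > 0:
        eta = eta + rng.normal(0.0, noise_sd, size=eta.shape)
    ra = expit(eta)
    sums = ra.sum(axis=0)
    over = sums > 1.0
    ra[:, over] = ra[:, over] / sums[over]
    return pd.DataFrame(ra, index=env_effects.index, columns=env.values.index)
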