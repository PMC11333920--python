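"""End-to-end orchestration of the analysis chain on one configuration.

Stages: simulate -> filter cascade -> diversity -> PERMANOVA / environment
screens -> per-genus models -> SparCC -> networks -> cohesion -> environment
correlations.  Every stochastic stage takes a seed derived from a single
master seed by fixed offsets, so any stage can be re-run in isolation and a
repeated run reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import network as nw
from . import simulate as sim
from . import tables as tb
from .envmodels import GenusEnvironmentModel, top_shared_genera
from .sparcc import SparCC

__all__ = ["RunConfig", "run_all", "validate_inputs"]

log = logging.getLogger("phyllonet")

_STAGE_OFFSETS = {
    "simulate": 1,
    "env": 2,
    "permanova": 3,
    "env_screen": 4,
    "sparcc": 5,
    "bootstrap": 6,
}


@dataclass
class RunConfig:
    """All thresholds and seeds for one pipeline run."""

    outdir: str = "phyllonet_run"
    seed: int = 0
    # synthetic design
    n_sites: int = 6
    n_timepoints: int = 11
    samples_per_site_per_timepoint: int = 3
    n_otus: dict = field(
        default_factory=lambda: {"bacteria": 30, "fungi": 12, "nfeuk": 8}
    )
    depth_range: tuple = (10_000, 100_000)
    richness_ratio: float = 2.0
    planted_correlations: dict = field(default_factory=dict)  # "i,j" -> rho
    # filters
    min_sample_reads: int = 50
    min_otu_reads: int = 50
    prevalence_min_samples: int = 5
    prevalence_min_reads: int = 10
    # inference
    n_permutations: int = 999
    n_bootstraps: int = 100
    p_max: float = 0.001
    sparcc_n_outer: int = 20
    sparcc_n_outer_boot: int = 5
    genus_max_subset: int = 4

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + _STAGE_OFFSETS[stage]) % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "depth_range" in raw:
            raw["depth_range"] = tuple(raw["depth_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["depth_range"] = list(d["depth_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def validate_inputs(counts_path=None, metadata_path=None, env_path=None) -> list[str]:
    """Cross-check user-supplied inputs; returns a list of problems (empty = ok)."""
    problems: list[str] = []
    md = None
    if metadata_path is not None:
        md = pd.read_csv(metadata_path, sep="\t", index_col=0)
        for col in ("compartment", "site", "season", "year", "timepoint"):
            if col not in md.columns:
                problems.append(f"metadata lacks required column {col!r}")
    if counts_path is not None:
        try:
            table = tb.read_count_table(counts_path)
        except Exception as err:  # surfaced verbatim to the report
            problems.append(f"count table unreadable: {err}")
            table = None
        if table is not None and md is not None:
            missing = set(table.sample_ids) - set(md.index)
            if missing:
                problems.append(
                    f"samples in counts absent from metadata: {sorted(missing)[:5]}"
                )
    if env_path is not None:
        try:
            env = tb.EnvTable.read_tsv(env_path)
            missing = set(tb.TERRACLIMATE_FACTORS) - set(env.factors)
            if missing:
                problems.append(f"environment table lacks factors: {sorted(missing)}")
        except Exception as err:
            problems.append(f"environment table unreadable: {err}")
    return problems


def _planted_truth(config: RunConfig) -> sim.SimTruth:
    D = sum(config.n_otus.values())
    planted = {
        tuple(int(x) for x in key.split(",")): float(rho)
        for key, rho in config.planted_correlations.items()
    }
    return sim.SimTruth.with_planted_pairs(
        D,
        planted=planted,
        compartment_richness_ratio=config.richness_ratio,
        seed=config.stage_seed("simulate"),
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Run the full chain on synthetic data; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, paths: list[Path], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _checksum(p) for p in paths},
            **info,
        }
        log.info("stage %s done: %s", stage, [p.name for p in paths])

    # --- simulate -------------------------------------------------------
    design = sim.SimDesign(
        n_sites=config.n_sites,
        n_timepoints=config.n_timepoints,
        samples_per_site_per_timepoint=config.samples_per_site_per_timepoint,
        sequencing_depth_range=tuple(config.depth_range),
        n_otus=dict(config.n_otus),
    )
    truth = _planted_truth(config)
    table, _ = sim.simulate_counts(truth, design)
    env = sim.simulate_env(design, seed=config.stage_seed("env"))
    env_z = env.zscore()
    counts_path, meta_path, env_path = (
        out / "counts.tsv",
        out / "metadata.tsv",
        out / "environment.tsv",
    )
    table.write_tsv(counts_path, metadata_path=meta_path)
    env.write_tsv(env_path)
    (out / "truth.json").write_text(
        json.dumps(
            {
                "seed": truth.seed,
                "planted_correlations": config.planted_correlations,
                "compartment_richness_ratio": truth.compartment_richness_ratio,
            },
            indent=2,
        )
    )
    record(
        "simulate",
        [counts_path, meta_path, env_path, out / "truth.json"],
        seed=config.stage_seed("simulate"),
        n_otus=table.n_otus,
        n_samples=table.n_samples,
    )

    # --- filter cascade -------------------------------------------------
    before = (table.n_otus, table.n_samples)
    table = tb.filter_low_depth_samples(table, config.min_sample_reads)
    table = tb.filter_rare_otus(table, config.min_otu_reads)
    filtered_path = out / "counts.filtered.tsv"
    table.write_tsv(filtered_path)
    record(
        "filter",
        [filtered_path],
        before={"otus": before[0], "samples": before[1]},
        after={"otus": table.n_otus, "samples": table.n_samples},
    )

    # --- diversity ------------------------------------------------------
    h = dv.shannon(table.counts)
    div_path = out / "shannon.tsv"
    h.rename_axis("sample").to_csv(div_path, sep="\t")
    record("diversity", [div_path])

    # --- PERMANOVA + environment screens --------------------------------
    dm = dv.bray_curtis(table.counts)
    res = dv.Permanova(
        dm, table.metadata, ["compartment", "site", "season"]
    ).fit(n_permutations=config.n_permutations, seed=config.stage_seed("permanova"))
    perm_path = out / "permanova.tsv"
    res.table.to_csv(perm_path, sep="\t")

    env_by_sample = env_z.align_to_samples(table.metadata)
    screen = dv.env_permanova_screen(
        dm, env_by_sample,
        n_permutations=config.n_permutations,
        seed=config.stage_seed("env_screen"),
    )
    screen_path = out / "env_permanova.tsv"
    screen.to_csv(screen_path, sep="\t")
    divcor = dv.diversity_env_correlation(h, env_by_sample)
    divcor_path = out / "diversity_env_spearman.tsv"
    divcor.to_csv(divcor_path, sep="\t")
    record("permanova", [perm_path, screen_path, divcor_path],
           n_permutations=config.n_permutations)

    # --- per-genus environmental models ---------------------------------
    from .envmodels import drop_collinear, prepare_genus_table

    env_for_models, collinear_report = drop_collinear(env_by_sample)
    for dropped, partner, r in collinear_report:
        log.info("dropped collinear factor %s (r=%.3f with %s)", dropped, r, partner)
    genus_results = {}
    for compartment in ("epiphyte", "endophyte"):
        samples = table.metadata.index[table.metadata["compartment"] == compartment]
        sub = table._subset(samples=samples)
        genus_ra = prepare_genus_table(sub, min_reads=config.min_otu_reads)
        model = GenusEnvironmentModel(
            genus_ra,
            env_for_models.loc[samples],
            compartment,
            max_subset_size=config.genus_max_subset,
        )
        genus_results[compartment] = model.fit()
    glm_path = out / "genus_env_models.tsv"
    pd.concat([r.table for r in genus_results.values()]).to_csv(
        glm_path, sep="\t", index=False
    )
    shared = top_shared_genera(
        genus_results["epiphyte"], genus_results["endophyte"], k=30
    )
    (out / "top_shared_genera.txt").write_text("\n".join(shared) + "\n")
    record("glm", [glm_path, out / "top_shared_genera.txt"])

    # --- networks + cohesion per stratum --------------------------------
    edge_frames, cohesion_frames, complexity_rows = [], [], []
    networks: dict = {}
    sparcc_seed = np.random.SeedSequence(config.stage_seed("sparcc"))
    for (timepoint, compartment), stratum in tb.split_strata(table):
        filtered = tb.network_prevalence_filter(
            stratum, config.prevalence_min_samples, config.prevalence_min_reads
        )
        if filtered.n_otus < 4:
            log.info("stratum %s/%s too sparse for SparCC; skipped",
                     timepoint, compartment)
            continue
        child = int(sparcc_seed.spawn(1)[0].generate_state(1)[0] % 2**31)
        result = SparCC(
            filtered.counts, n_outer=config.sparcc_n_outer
        ).fit(
            n_bootstraps=config.n_bootstraps,
            seed=child,
            n_outer_boot=config.sparcc_n_outer_boot,
        )
        net = nw.build_network(result, p_max=config.p_max,
                               stratum=(timepoint, compartment))
        networks[(timepoint, compartment)] = net
        edge_frames.append(net.edge_list())
        n_nodes, n_edges, pos_frac = nw.network_complexity(net)
        complexity_rows.append(
            {
                "timepoint": timepoint,
                "compartment": compartment,
                "n_nodes": n_nodes,
                "n_edges": n_edges,
                "pos_edge_fraction": pos_frac,
            }
        )
        conn = nw.connectivity_values(result, p_max=config.p_max)
        ra = tb.to_relative_abundance(filtered.counts)
        coh = nw.cohesion(ra, conn)
        cf = coh.samples.copy()
        cf["timepoint"], cf["compartment"] = timepoint, compartment
        cohesion_frames.append(cf)
    edges_path, comp_path, coh_path = (
        out / "network_edges.tsv",
        out / "network_complexity.tsv",
        out / "cohesion.tsv",
    )
    (pd.concat(edge_frames) if edge_frames else pd.DataFrame()).to_csv(
        edges_path, sep="\t", index=False
    )
    complexity = pd.DataFrame(complexity_rows)
    complexity.to_csv(comp_path, sep="\t", index=False)
    cohesion_all = (
        pd.concat(cohesion_frames) if cohesion_frames else pd.DataFrame()
    )
    cohesion_all.rename_axis("sample").to_csv(coh_path, sep="\t")
    # nodes conserved between consecutive time points, per compartment
    inherited_rows = []
    for compartment in ("epiphyte", "endophyte"):
        tps = sorted(t for t, c in networks if c == compartment)
        for a, b in zip(tps, tps[1:]):
            shared = nw.inherited_nodes(
                networks[(a, compartment)], networks[(b, compartment)]
            )
            inherited_rows.append(
                {
                    "compartment": compartment,
                    "from_timepoint": a,
                    "to_timepoint": b,
                    "n_inherited": len(shared),
                }
            )
    inh_path = out / "inherited_nodes.tsv"
    pd.DataFrame(inherited_rows).to_csv(inh_path, sep="\t", index=False)
    record("network", [edges_path, comp_path, coh_path, inh_path],
           n_strata=len(complexity_rows))

    # --- environment correlations of complexity and cohesion ------------
    outputs = [out / "config.yaml", out / "manifest.json"]
    if not complexity.empty and not cohesion_all.empty:
        key = sim.SimDesign(
            n_sites=config.n_sites, n_timepoints=config.n_timepoints
        ).timepoint_key()
        env_tp = env_z.per_timepoint_mean(key)
        rows = []
        for compartment, grp in complexity.groupby("compartment"):
            per_tp = grp.set_index("timepoint")[["n_nodes"]]
            cor = nw.complexity_env_correlation(per_tp, env_tp)
            cor["compartment"] = compartment
            rows.append(cor.reset_index())
        nodes_env = pd.concat(rows)
        nodes_env_path = out / "nodes_env_pearson.tsv"
        nodes_env.to_csv(nodes_env_path, sep="\t", index=False)

        md = table.metadata.loc[cohesion_all.index]
        env_for_cohesion = env_z.align_to_samples(md)
        coh_env = nw.cohesion_env_correlation(cohesion_all["total"], env_for_cohesion)
        coh_env_path = out / "cohesion_env_spearman.tsv"
        coh_env.to_csv(coh_env_path, sep="\t")
        record("env_network", [nodes_env_path, coh_env_path])

    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
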