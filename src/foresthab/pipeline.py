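"""End-to-end analysis pipeline driven by one YAML config.

Runs the stages in dependency order on a real (CSV) or synthetic census:

    simulate -> grid -> [metrics, dispersion, rda, network, torus -> summarize,
                         indval, pcf]

Every run directory gets a ``run.json`` provenance record (config hash,
seed, package/numpy versions, stage parameters) and a plain-text log; each
stage output CSV gets a ``<name>.meta.json`` sidecar carrying the same
provenance so a file separated from its run directory stays attributable.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .census import (
    CensusTable,
    filter_min_abundance,
    grid_stems,
    read_census,
    write_census,
)
from .community import importance_values, kruskal_wallis, occurrence_overlap, species_accumulation
from .habitat import build_combined_map, torus_test
from .indicators import indval
from .multivariate import betadisper, bray_curtis, rda_marginal
from .network import build_network, connectance, h2_bounds, h2_entropy, h2prime
from .pointpattern import mc_envelope
from .summarize import summarize_associations
from .synthetic import PreferenceSpec, apply_preferences, default_config, generate_census

__all__ = ["run_pipeline", "synthetic_topography"]

ALL_STAGES = [
    "simulate",
    "grid",
    "metrics",
    "dispersion",
    "rda",
    "network",
    "torus",
    "indval",
    "pcf",
    "summarize",
]


def synthetic_topography(qm, seed: int = 0) -> pd.DataFrame:
    """Smooth synthetic per-quadrat topography (elevation, slope, aspect,
    convexity) for exercising the RDA stage when no survey is available."""
    rng = np.random.default_rng(seed)
    meta = qm.quadrat_meta
    ix = meta["cell_ix"].to_numpy(dtype=float)
    iy = meta["cell_iy"].to_numpy(dtype=float)
    plot_off = pd.factorize(meta["plot"])[0] * 7.5
    elev = 1500 + plot_off + 3.0 * ix + 2.0 * iy + rng.normal(0, 1.5, len(meta))
    slope = np.clip(40 + 8 * np.sin(ix / 3.0) + rng.normal(0, 4, len(meta)), 0, 80)
    aspect = (360 * (iy / 10.0) + rng.normal(0, 20, len(meta))) % 360
    convexity = rng.normal(0, 1, len(meta))
    return pd.DataFrame(
        {
            "plot": meta["plot"].to_numpy(),
            "cell_ix": meta["cell_ix"].to_numpy(),
            "cell_iy": meta["cell_iy"].to_numpy(),
            "elevation": elev,
            "slope": slope,
            "aspect": aspect,
            "convexity": convexity,
        }
    )


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: dict, out_dir: Path):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.alpha = float(config.get("alpha", 0.05))
        self.min_abundance = int(config.get("min_abundance", 5))
        self.census: CensusTable | None = None
        self.qm = None
        self.associations: pd.DataFrame | None = None
        self.log_lines: list[str] = []
        self.provenance = {
            "package": "foresthab",
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
            "config_hash": _config_hash(config),
            "seed": self.seed,
        }

    def log(self, msg: str) -> None:
        self.log_lines.append(msg)

    def write_csv(self, df: pd.DataFrame, name: str, **kwargs) -> Path:
        path = self.out / name
        df.to_csv(path, **kwargs)
        meta = dict(self.provenance)
        meta["output"] = name
        (self.out / f"{name}.meta.json").write_text(json.dumps(meta, indent=2))
        return path

    def write_json(self, obj, name: str) -> Path:
        path = self.out / name
        payload = {"provenance": self.provenance, "result": obj}
        path.write_text(json.dumps(payload, indent=2, default=float))
        return path


def _load_census(run: PipelineRun) -> CensusTable:
    spec = run.config.get("census", {})
    if "csv" in spec:
        run.log(f"reading census from {spec['csv']}")
        return read_census(spec["csv"])
    syn = spec.get("synthetic", {})
    cfg = default_config(
        n_species=int(syn.get("n_species", 20)),
        mean_abundance=float(syn.get("mean_abundance", 120.0)),
        seed=run.seed,
        n_plots=int(syn.get("n_plots", 4)),
    )
    prefs = [
        PreferenceSpec(p["species"], p["plot"], float(p["fold"]))
        for p in spec.get("preferences", [])
    ]
    if prefs:
        cfg = apply_preferences(cfg, prefs)
    run.log(f"simulating census: {len(cfg.species_pool)} species, seed {run.seed}")
    return generate_census(cfg)


def _require(run: PipelineRun, attr: str, producer: str):
    value = getattr(run, attr)
    if value is None:
        raise RuntimeError(
            f"stage input {attr!r} missing: enable the {producer!r} stage first"
        )
    return value


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the configured stages; returns the run directory.

    ``config`` is a YAML path or an equivalent dict; see the README for the
    schema.  Outputs are deterministic under a fixed config + seed (file
    timestamps aside).
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    run = PipelineRun(config, Path(out_dir))
    stages = config.get("stages", ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    for stage in [s for s in ALL_STAGES if s in stages]:
        run.log(f"stage {stage}: start")
        if stage == "simulate":
            run.census = _load_census(run)
            buf_path = run.out / "census.csv"
            write_census(run.census, buf_path)
            run.log(f"census: {run.census.n_stems} stems, "
                    f"{len(run.census.species)} species")
        elif stage == "grid":
            census = _require(run, "census", "simulate")
            run.qm = grid_stems(census)
            run.write_csv(run.qm.abundance, "quadrat_matrix.csv",
                          index_label="species")
        elif stage == "metrics":
            qm = _require(run, "qm", "grid")
            census = _require(run, "census", "simulate")
            ivs = []
            rich, abund = [], []
            for p in census.plots:
                ivs.append(importance_values(qm, census, p.plot_id)
                           .assign(species=lambda d: d.index))
                mask = qm.quadrat_meta["plot"].to_numpy() == p.plot_id
                sub = qm.abundance.loc[:, mask]
                rich.append((sub > 0).sum(axis=0).to_numpy())
                abund.append(sub.sum(axis=0).to_numpy())
            run.write_csv(pd.concat(ivs), "importance_values.csv", index=False)
            curve = species_accumulation(qm)
            run.write_csv(curve.to_frame(), "accumulation.csv", index=False)
            h_r, p_r = kruskal_wallis(rich)
            h_a, p_a = kruskal_wallis(abund)
            overlap = occurrence_overlap(qm)
            run.write_json(
                {
                    "kruskal_richness": {"H": h_r, "p": p_r},
                    "kruskal_abundance": {"H": h_a, "p": p_a},
                    "overlap_at_least": {str(k): v for k, v in
                                         overlap["at_least"].items()},
                    "overlap_subsets": {"+".join(k): v for k, v in
                                        overlap["subsets"].items()},
                },
                "community_metrics.json",
            )
        elif stage == "dispersion":
            qm = _require(run, "qm", "grid")
            d = bray_curtis(qm, drop_empty=True)
            groups = [lbl.split(":")[0] for lbl in d.index]
            res = betadisper(d, groups, n_perm=199, seed=run.seed)
            run.write_json(
                {
                    "f_stat": res.f_stat,
                    "p_anova": res.p_anova,
                    "p_perm": res.p_perm,
                    "group_mean_dist": res.group_means().to_dict(),
                },
                "dispersion.json",
            )
        elif stage == "rda":
            qm = _require(run, "qm", "grid")
            topo_path = run.config.get("topography_csv")
            topo = (pd.read_csv(topo_path) if topo_path
                    else synthetic_topography(qm, seed=run.seed))
            res = rda_marginal(qm, topo, n_perm=199, seed=run.seed)
            run.write_csv(res.table, "rda_marginal.csv", index=False)
        elif stage == "network":
            qm = _require(run, "qm", "grid")
            net = build_network(qm)
            run.write_csv(net.matrix, "network_matrix.csv", index_label="species")
            run.write_csv(net.edge_list(), "network_edges.csv", index=False)
            h2min, h2max = h2_bounds(net)
            run.write_json(
                {
                    "H2": h2_entropy(net),
                    "H2min": h2min,
                    "H2max": h2max,
                    "H2prime": h2prime(net),
                    "connectance": connectance(net),
                },
                "network_indices.json",
            )
        elif stage == "torus":
            qm = _require(run, "qm", "grid")
            census = _require(run, "census", "simulate")
            qf = filter_min_abundance(qm, run.min_abundance)
            hmap = build_combined_map(census)
            run.associations = torus_test(qf, hmap, alpha=run.alpha)
            run.write_csv(run.associations, "associations.csv", index=False)
        elif stage == "indval":
            qm = _require(run, "qm", "grid")
            qf = filter_min_abundance(qm, run.min_abundance)
            res = indval(qf, n_perm=499, seed=run.seed)
            run.write_csv(res, "indval.csv", index=False)
        elif stage == "pcf":
            census = _require(run, "census", "simulate")
            top = (
                census.stems.groupby("species").size().sort_values(ascending=False)
            )
            targets = [s for s in top.index[:2] if top[s] >= 30]
            results = {}
            for sp in targets:
                for p in census.plots:
                    pts = census.stems.query("species == @sp and plot == @p.plot_id")
                    if len(pts) < 30:
                        continue
                    est = mc_envelope(
                        pts[["x", "y"]].to_numpy(),
                        (p.width, p.height),
                        n_sim=199,
                        coverage=0.99,
                        seed=run.seed,
                    )
                    name = f"pcf_{sp}_{p.plot_id}.csv"
                    run.write_csv(est.to_frame(), name, index=False)
                    results[name] = int(est.n_sim)
            run.log(f"pcf: {len(results)} patterns analyzed")
        elif stage == "summarize":
            at = _require(run, "associations", "torus")
            summary = summarize_associations(at)
            run.write_json(summary.to_dict(), "association_summary.json")
        run.log(f"stage {stage}: done")

    (run.out / "run.json").write_text(
        json.dumps({"provenance": run.provenance, "config": config,
                    "stages": stages}, indent=2, default=str)
    )
    (run.out / "run.log").write_text("\n".join(run.log_lines) + "\n")
    return run.out
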