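"""End-to-end orchestration: filter -> popgen tables -> connectivity -> MLPE.

Runs are driven by a :class:`RunConfig` that either names input files (VCF,
metadata CSV, landcover raster) or embeds a synthetic scenario.  Every run
writes its artifacts plus a JSON manifest (config echo, per-stage record
counts, wall-clock, warnings) into the output directory; a rerun with the
same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import build_transition_graph, lcp_distance, passage_map
from .genotype_io import (
    FilterConfig,
    GenotypeMatrix,
    apply_filter_chain,
    group_by_location,
    read_metadata,
    read_vcf,
    remove_high_missing_individuals,
)
from .mlpe import run_model_suite
from .popgen import (
    diversity_summary,
    fit_hs_urban,
    genetic_distance,
    standardized_heterozygosity,
    wc_fst,
)
from .resistance import (
    build_resistance_surface,
    load_hypotheses,
    read_landcover,
    urban_proportion,
    write_ascii_grid,
)
from .synthetic_data import (
    SyntheticScenario,
    default_landscape_spec,
    degrade_to_vcf_records,
    generate_landscape,
    sample_locations,
    simulate_ibr_genotypes,
    simulate_island_genotypes,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # file inputs (used when no scenario is given)
    vcf: str | None = None
    metadata: str | None = None
    landcover: str | None = None
    hypotheses_file: str | None = None
    # synthetic scenario
    scenario: SyntheticScenario | None = None
    scenario_kind: str = "island"  # island | ibr | ibd
    # knobs
    filters: FilterConfig = field(default_factory=FilterConfig)
    buffer_radii: tuple[float, float] = (1000.0, 3000.0)
    grouping_radius: float = 1000.0
    epsilon: float = 1e-4
    neighbours: int = 8
    hypothesis_names: tuple[str, ...] = ("NULL", "EMP")
    n_locations: int = 20
    n_per_location: int = 1
    fst_bootstrap: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "filters" in raw:
            raw["filters"] = FilterConfig(**raw["filters"])
        if "scenario" in raw and raw["scenario"] is not None:
            raw["scenario"] = SyntheticScenario(**raw["scenario"])
        for key in ("buffer_radii", "hypothesis_names"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, FilterConfig):
                out[k] = v.__dict__
            elif isinstance(v, SyntheticScenario):
                out[k] = {kk: vv for kk, vv in v.__dict__.items() if kk != "landscape"}
            elif isinstance(v, tuple):
                out[k] = list(v)
            else:
                out[k] = v
        return out


class _Manifest:
    def __init__(self, cfg: RunConfig):
        self.t0 = time.time()
        cfg_json = json.dumps(cfg.to_jsonable(), sort_keys=True, default=str)
        self.data = {
            "version": __version__,
            "config": cfg.to_jsonable(),
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
            "stages": {},
            "warnings": [],
            "status": "running",
        }

    def stage(self, name: str, **counts) -> None:
        self.data["stages"][name] = counts

    def warn(self, msg: str) -> None:
        self.data["warnings"].append(msg)

    def write(self, out_dir: Path, status: str) -> None:
        self.data["status"] = status
        self.data["wall_clock_s"] = round(time.time() - self.t0, 3)
        (out_dir / "manifest.json").write_text(json.dumps(self.data, indent=1, default=str))


def _load_or_simulate_genotypes(cfg: RunConfig, manifest: _Manifest):
    """Returns (GenotypeMatrix, population labels, metadata or None)."""
    if cfg.scenario is not None:
        sc = cfg.scenario
        gm, pops = simulate_island_genotypes(
            sc.n_pops, sc.n_individuals_per_pop, sc.n_loci, sc.fst_target,
            seed=cfg.seed,
        )
        samples, records = degrade_to_vcf_records(
            gm, missing_rate=sc.missing_rate, seed=cfg.seed + 1
        )
        gm, report = apply_filter_chain(samples, records, cfg.filters)
        gm, removed = remove_high_missing_individuals(gm, cfg.filters.max_individual_missing)
        manifest.stage(
            "filter",
            sites_in=report.counts()[0],
            sites_out=report.counts()[-1],
            individuals_removed=len(removed),
        )
        pops = pops.loc[gm.samples]
        return gm, pops, None
    if cfg.vcf is None or cfg.metadata is None:
        raise PipelineError("either a scenario or vcf+metadata inputs are required")
    samples, records = read_vcf(cfg.vcf)
    gm, report = apply_filter_chain(samples, records, cfg.filters)
    gm, removed = remove_high_missing_individuals(gm, cfg.filters.max_individual_missing)
    manifest.stage(
        "filter",
        sites_in=report.counts()[0],
        sites_out=report.counts()[-1],
        individuals_removed=len(removed),
    )
    meta = read_metadata(cfg.metadata)
    meta = meta[meta["id"].isin(gm.samples)].reset_index(drop=True)
    if "location" in meta.columns and meta["location"].notna().all():
        pops = meta.set_index("id")["location"]
    else:
        pops = group_by_location(meta, cfg.grouping_radius)
    pops = pops.reindex(gm.samples)
    empty = pops.isna()
    if empty.any():
        raise PipelineError(f"samples without a population label: {list(pops.index[empty])}")
    counts = pops.value_counts()
    if (counts < 1).any():
        raise PipelineError(f"empty population: {counts[counts < 1].index.tolist()}")
    return gm, pops, meta


def run_popgen_pipeline(cfg: RunConfig) -> dict:
    """Filter, summarise diversity and differentiation, write tables.

    Artifacts: diversity_summary.tsv, fst_overall.json, fst_pairwise.tsv,
    hs_table.csv, optionally hs_urban_fit.json, plus manifest.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            gm, pops, meta = _load_or_simulate_genotypes(cfg, manifest)
            artifacts: dict = {"genotypes": gm, "pops": pops}

            hs = standardized_heterozygosity(gm)
            hs.to_csv(out / "hs_table.csv")
            artifacts["hs"] = hs

            summary = diversity_summary(gm, pops)
            summary.to_csv(out / "diversity_summary.tsv", sep="\t")
            artifacts["diversity"] = summary

            overall = wc_fst(gm, pops, n_boot=cfg.fst_bootstrap, seed=cfg.seed + 2)
            (out / "fst_overall.json").write_text(
                json.dumps(
                    {
                        "theta": overall.estimate,
                        "ci": [overall.ci_lower, overall.ci_upper],
                        "n_loci": overall.n_loci_used,
                    }
                )
            )
            pair = wc_fst(gm, pops, pairwise=True)
            pair.to_csv(out / "fst_pairwise.tsv", sep="\t")
            artifacts["fst_overall"] = overall
            artifacts["fst_pairwise"] = pair
            manifest.stage("popgen", n_samples=gm.n_samples, n_loci=gm.n_loci,
                           n_pops=int(pops.nunique()))

            if cfg.landcover is not None and meta is not None:
                lc = read_landcover(cfg.landcover)
                fits = {}
                for radius in cfg.buffer_radii:
                    urb = np.array(
                        [
                            urban_proportion(lc, (x, y), radius)
                            for x, y in zip(meta["x"], meta["y"])
                        ]
                    )
                    fit, autocorr = fit_hs_urban(
                        hs["hs"].reindex(meta["id"]).to_numpy(),
                        urb,
                        coords=meta[["x", "y"]].to_numpy(),
                    )
                    fits[f"{int(radius)}m"] = {
                        **fit,
                        "residual_moran_I": autocorr.I,
                        "residual_moran_p": autocorr.p_value,
                    }
                (out / "hs_urban_fit.json").write_text(json.dumps(fits, indent=1))
                artifacts["hs_urban"] = fits
            for w in caught:
                manifest.warn(str(w.message))
    except Exception:
        manifest.write(out, "failed")
        raise
    manifest.write(out, "ok")
    artifacts["manifest"] = manifest.data
    return artifacts


def run_connectivity_pipeline(cfg: RunConfig) -> dict:
    """Distances, MLPE model suite, passage map and routes for one area."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            hyps_all = load_hypotheses(cfg.hypotheses_file)
            hyps = {n: hyps_all[n] for n in cfg.hypothesis_names}
            if cfg.scenario is not None:
                sc = cfg.scenario
                lc = generate_landscape(sc.landscape or default_landscape_spec(), cfg.seed)
                truth = "EMP" if cfg.scenario_kind == "ibr" else "NULL"
                surface = build_resistance_surface(lc, hyps_all[truth])
                locs = sample_locations(surface, cfg.n_locations, seed=cfg.seed + 3)
                sigma2 = sc.ibr_sigma2 if cfg.scenario_kind == "ibr" else sc.ibr_sigma2
                gm, meta = simulate_ibr_genotypes(
                    locs,
                    surface,
                    sc.n_loci,
                    phi=sc.ibr_scale_phi,
                    sigma2=sigma2,
                    seed=cfg.seed + 4,
                    n_per_location=cfg.n_per_location,
                    epsilon=cfg.epsilon,
                )
                points = meta[["id", "x", "y"]]
            else:
                if None in (cfg.vcf, cfg.metadata, cfg.landcover):
                    raise PipelineError("connectivity needs vcf, metadata and landcover")
                samples, records = read_vcf(cfg.vcf)
                gm, _ = apply_filter_chain(samples, records, cfg.filters)
                gm, _ = remove_high_missing_individuals(gm, cfg.filters.max_individual_missing)
                meta = read_metadata(cfg.metadata)
                meta = meta[meta["id"].isin(gm.samples)].reset_index(drop=True)
                lc = read_landcover(cfg.landcover)
                points = meta[["id", "x", "y"]]
            gdist = genetic_distance(gm)
            table, fits = run_model_suite(
                gdist,
                lc,
                hyps,
                points,
                include_distance_term=True,
                epsilon=cfg.epsilon,
                neighbours=cfg.neighbours,
            )
            table.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
            manifest.stage("mlpe", n_models=len(table), n_pairs=int(table["n_pairs"].iloc[0]))

            # passage map and LCP routes under the best-supported hypothesis
            best = table[table["best"]].iloc[0]["hypothesis"]
            surface_best = build_resistance_surface(lc, hyps[best])
            g_eps = build_transition_graph(surface_best, epsilon=cfg.epsilon,
                                           neighbours=cfg.neighbours)
            pm = passage_map(g_eps, points)
            write_ascii_grid(pm.values, pm.resolution, pm.origin, out / "passage.asc")
            g_lcp = build_transition_graph(surface_best, epsilon=0.0,
                                           neighbours=cfg.neighbours)
            _, paths = lcp_distance(g_lcp, points, return_paths=True)
            paths.to_frame().to_csv(out / "lcp_routes.csv", index=False)
            (out / "lcp_routes.geojson").write_text(json.dumps(paths.to_geojson(g_lcp)))
            manifest.stage("maps", best_hypothesis=str(best))
            for w in caught:
                manifest.warn(str(w.message))
            artifacts = {
                "comparison": table,
                "fits": fits,
                "passage": pm,
                "paths": paths,
                "manifest": manifest.data,
            }
    except Exception:
        manifest.write(out, "failed")
        raise
    manifest.write(out, "ok")
    return artifacts


def load_gated_fixture(genotype_csv, populations_csv) -> tuple[GenotypeMatrix, pd.Series]:
    """Load a deposited SNP table plus population assignments, when present.

    ``genotype_csv``: sample-by-SNP table of 0/1/2 alt dosages with NA for
    missing, first column sample id.  ``populations_csv``: columns
    id,population.  Returns the matrix restricted to assigned samples.
    """
    gm = GenotypeMatrix.from_csv(genotype_csv)
    pops = pd.read_csv(populations_csv, dtype=str).set_index("id")["population"]
    keep = [i for i, s in enumerate(gm.samples) if s in pops.index]
    gm = gm.take_samples(keep)
    return gm, pops.reindex(gm.samples)
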