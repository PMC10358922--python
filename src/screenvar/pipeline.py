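"""End-to-end pipeline: standardise -> GLM -> CAR smoothing -> MEET -> benchmark.

Each stage writes its own output files under the configured directory and
every table carries the configuration hash; all randomness flows from one
global seed through named per-stage substreams.
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

from . import __version__
from .adjacency import Adjacency
from .benchmark import centile_threshold, missed_screens
from .broad_models import fit_rate_model, lrt_nb_vs_poisson, marginal_sprr, wald_tests
from .car import MCMCConfig, fit_leroux_car, map_bins, posterior_summaries
from .heterogeneity import meet
from .io import read_adjacency, read_areas, read_counts
from .standardization import (
    ELIGIBILITY_SCHEDULE,
    ScreeningCounts,
    apply_exclusions,
    compute_spr,
    expected_counts,
    national_age_rates,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_rng"]

log = logging.getLogger("screenvar")

# stable substream codes per stage
STAGE_CODES = {"simulate": 1, "standardize": 2, "glm": 3, "smooth": 4,
               "meet": 5, "benchmark": 6}


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    """Named per-stage substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(global_seed), STAGE_CODES[stage]]))


@dataclass
class PipelineConfig:
    """Paths, period and settings for a full pipeline run."""

    area_counts: str
    areas: str
    adjacency: str | None = None
    national_counts: str | None = None
    period: str = "2019-2020"
    min_mean_pop: float = 5.0
    mcmc: MCMCConfig = field(default_factory=MCMCConfig.test_profile)
    meet_n_mc: int = 999
    meet_use_smoothed: bool = True
    benchmark_centile: float = 80.0
    output_dir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = ("standardize", "glm", "smooth", "meet", "benchmark")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "mcmc" in raw:
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        # hash the analytic configuration; where outputs land is not part
        # of what determines the estimates
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        for name in ("area_counts", "areas"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.national_counts and not Path(self.national_counts).exists():
            raise FileNotFoundError(f"national counts file not found: {self.national_counts}")
        if "smooth" in self.stages:
            if not self.adjacency:
                raise ValueError("CAR smoothing requested but no adjacency file configured")
            if not Path(self.adjacency).exists():
                raise FileNotFoundError(f"adjacency file not found: {self.adjacency}")


def _stamp(df: pd.DataFrame, cfg_hash: str) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = cfg_hash
    return df


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages in order, writing per-stage outputs, a run
    log and a provenance record.  Deterministic given the global seed."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    provenance = {
        "config_hash": h,
        "seed": cfg.seed,
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages_completed": [],
    }

    counts = read_counts(cfg.area_counts, cfg.national_counts)
    areas = read_areas(cfg.areas)
    counts = ScreeningCounts(
        area=counts.area[counts.area["period"] == cfg.period].reset_index(drop=True),
        national=counts.national,
    )
    areas, counts, exclusion_log = apply_exclusions(areas, counts, cfg.min_mean_pop)
    (out / "exclusions.jsonl").write_text(
        "\n".join(json.dumps(e) for e in exclusion_log) + ("\n" if exclusion_log else "")
    )
    log.info("loaded %d areas, %d count records after exclusions",
             len(areas), len(counts.area))

    adj = None
    if cfg.adjacency:
        adj = read_adjacency(cfg.adjacency)
        keep = [i for i, a in enumerate(adj.ids) if a in set(areas["area_id"])]
        if len(keep) != adj.n:
            W = adj.W[np.ix_(keep, keep)]
            adj = Adjacency(ids=[adj.ids[i] for i in keep], W=W)
        areas = areas.set_index("area_id").loc[adj.ids].reset_index()

    results: dict = {}
    try:
        rates = national_age_rates(counts)
        expected = expected_counts(areas, ELIGIBILITY_SCHEDULE, rates, cfg.period)
        spr = compute_spr(counts, expected)
        if "standardize" in cfg.stages:
            _stamp(expected, h).to_csv(out / "expected_counts.csv", index=False)
            _stamp(spr, h).to_csv(out / "spr.csv", index=False)
            provenance["stages_completed"].append("standardize")

        if "glm" in cfg.stages:
            nb = fit_rate_model(counts, expected, areas, family="negative_binomial")
            pois = fit_rate_model(counts, expected, areas, family="poisson")
            stat, p = lrt_nb_vs_poisson(nb, pois)
            _stamp(nb.prr, h).to_csv(out / "glm_prr.csv", index=False)
            sprr_frames = [marginal_sprr(nb, c).assign(factor=c) for c in nb.covariates]
            if sprr_frames:
                _stamp(pd.concat(sprr_frames), h).to_csv(out / "sprr.csv", index=False)
            (out / "glm_tests.json").write_text(json.dumps({
                "lrt_nb_vs_poisson": {"statistic": stat, "p": p},
                "wald": wald_tests(nb),
                "nb_dispersion": nb.dispersion,
                "config_hash": h,
            }, indent=1))
            results["glm"] = nb
            provenance["stages_completed"].append("glm")

        summaries = None
        if "smooth" in cfg.stages:
            assert adj is not None
            mcfg = dataclasses.replace(cfg.mcmc, seed=int(
                stage_rng(cfg.seed, "smooth").integers(2**31)))
            E = expected.set_index("area_id").loc[adj.ids, "expected"].to_numpy()
            y = counts.area.set_index("area_id").loc[adj.ids, "screened"].to_numpy(float)
            post = fit_leroux_car(y, E, adj, mcfg)
            summaries = posterior_summaries(post, period=cfg.period)
            raw = spr.set_index("area_id").loc[adj.ids, "spr"].to_numpy()
            summaries.insert(2, "spr_raw", raw)
            bins, breaks = map_bins(summaries["sspr"].to_numpy())
            summaries["map_bin"] = bins
            _stamp(summaries, h).to_csv(out / "car_summaries.csv", index=False)
            (out / "car_diagnostics.json").write_text(json.dumps({
                "acceptance": post.acceptance,
                "rho_median": float(np.median(post.rho)),
                "tau2_median": float(np.median(post.tau2)),
                "map_breaks": breaks.tolist(),
                "config_hash": h,
            }, indent=1))
            results["car"] = post
            provenance["stages_completed"].append("smooth")

        if "meet" in cfg.stages:
            cent = areas[["centroid_x", "centroid_y"]].to_numpy(float)
            E = expected.set_index("area_id").loc[areas["area_id"], "expected"].to_numpy()
            if cfg.meet_use_smoothed and summaries is not None:
                c = summaries.set_index("area_id").loc[areas["area_id"], "smoothed_count"].to_numpy()
            else:
                c = counts.area.set_index("area_id").loc[areas["area_id"], "screened"].to_numpy(float)
            res = meet(c, E, cent, n_mc=cfg.meet_n_mc,
                       rng=stage_rng(cfg.seed, "meet"))
            (out / "meet.json").write_text(json.dumps({
                "adjusted_p": res.adjusted_p, "p_min": res.p_min,
                "p_string": res.p_string(),
                "lambda_at_min": res.lambda_at_min,
                "lambda_grid": res.lambda_grid.tolist(),
                "statistic_per_lambda": res.statistic_per_lambda.tolist(),
                "p_per_lambda": res.p_per_lambda.tolist(),
                "n_mc": res.n_mc, "config_hash": h,
            }, indent=1))
            results["meet"] = res
            provenance["stages_completed"].append("meet")

        if "benchmark" in cfg.stages:
            if summaries is not None:
                sspr = summaries.set_index("area_id").loc[areas["area_id"], "sspr"].to_numpy()
            else:
                sspr = spr.set_index("area_id").loc[areas["area_id"], "spr"].to_numpy()
            E = expected.set_index("area_id").loc[areas["area_id"], "expected"].to_numpy()
            thr = centile_threshold(sspr, cfg.benchmark_centile)
            bench = missed_screens(sspr, E, thr, counts=counts,
                                   centile=cfg.benchmark_centile)
            pd.DataFrame({
                "area_id": areas["area_id"],
                "extra_screens": bench.extra_per_area,
                "config_hash": h,
            }).to_csv(out / "benchmark_areas.csv", index=False)
            (out / "benchmark.json").write_text(json.dumps({
                "centile": bench.centile,
                "threshold_sspr": bench.threshold_sspr,
                "total_extra": bench.total_extra,
                "extra_pct_of_screened": bench.extra_pct_of_screened,
                "baseline_rate": bench.baseline_rate,
                "counterfactual_rate": bench.counterfactual_rate,
                "config_hash": h,
            }, indent=1))
            results["benchmark"] = bench
            provenance["stages_completed"].append("benchmark")
    except Exception as err:
        provenance["failed_stage"] = str(err)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
        raise RuntimeError(
            f"pipeline failed after stages {provenance['stages_completed']}: {err}"
        ) from err

    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return out
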