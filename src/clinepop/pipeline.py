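"""End-to-end orchestration: simulate/load -> QC filter -> outlier scans ->
neutral F_ST -> P_ST-F_ST -> matrix regression -> trait regressions.

One config drives the whole run; every stage logs its locus/sample counts and
lands in a consolidated JSON report. Loci flagged by the F_ST outlier scan are
excluded before global/pairwise F_ST so that the neutral reference really is
neutral, and the same neutral multilocus theta is the F_ST reference of every
P_ST curve.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diffstats, filters, landscape, morpho, outliers, pstfst
from .genio import GenotypeTable, read_env_table, read_pop_map, read_trait_table, read_vcf
from .simdata import SimulationConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs. Exactly one of (simulation, input paths) is set."""

    simulation: SimulationConfig | None = None
    vcf: str | None = None
    pop_map: str | None = None
    env_table: str | None = None
    trait_table: str | None = None
    filter: filters.FilterConfig = dataclasses.field(default_factory=filters.FilterConfig)
    scan_q_threshold: float = 0.05
    rda_sd_mult: float = 3.0
    lfa_k: int = 1
    env_predictor: str = "bio12"
    fst_n_boot: int = 1000
    pst_n_boot: int = 1000
    pst_grid_n: int = 100
    pst_exclude: tuple[str, ...] = ("mass",)
    mmrr_n_perm: int = 1000
    ld_prune_for_pca: bool = True
    outdir: str = "clinepop_run"
    seed: int = 0

    def __post_init__(self) -> None:
        sim = self.simulation is not None
        paths = self.vcf is not None
        if sim == paths:
            raise ValueError(
                "exactly one of an embedded simulation or input paths must be given"
            )
        if paths and (self.pop_map is None or self.env_table is None):
            raise ValueError("input paths require vcf, pop_map and env_table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "filter" in raw:
            raw["filter"] = filters.FilterConfig(**raw["filter"])
        if "pst_exclude" in raw:
            raw["pst_exclude"] = tuple(raw["pst_exclude"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant config (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(
            payload,
            sort_keys=True,
            default=lambda o: o.__dict__ if hasattr(o, "__dict__") else str(o),
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        ds = generate_dataset(config.simulation)
        return ds.genotypes, ds.env_table, ds.traits, ds.truth
    table = read_vcf(config.vcf, pop_map=read_pop_map(config.pop_map))
    if isinstance(table, tuple):
        table = table[0]
    env = read_env_table(config.env_table)
    traits = (
        read_trait_table(config.trait_table) if config.trait_table else None
    )
    return table, env, traits, None


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage in dependency order; returns (and writes) the report.

    A stage that raises marks itself failed in the report; stages depending
    on its output are marked skipped. The report carries the config hash and
    the root seed, and is byte-stable for a fixed config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {
        name: np.random.default_rng(s)
        for name, s in zip(("fst", "pst", "mmrr"), root.spawn(3))
    }
    report: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name: str, fn, *deps: str):
        failed = [d for d in deps if report["stages"].get(d, {}).get("status") != "ok"]
        if failed:
            report["stages"][name] = {"status": "skipped", "blocked_by": failed}
            logger.warning("stage %s skipped (blocked by %s)", name, failed)
            return None
        try:
            payload = fn()
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            return None
        report["stages"][name] = {"status": "ok", **payload.pop("_summary", {})}
        logger.info("stage %s ok", name)
        return payload

    # -- data ------------------------------------------------------------
    state: dict[str, Any] = {}

    def data_stage():
        table, env, traits, truth = _load_inputs(config)
        state.update(table=table, env=env, traits=traits, truth=truth)
        return {
            "_summary": {
                "n_samples": table.n_samples,
                "n_loci": table.n_loci,
                "n_populations": len(table.pop_indices()),
            }
        }

    stage("data", data_stage)

    # -- filter ----------------------------------------------------------
    def filter_stage():
        filtered, rep = filters.apply_filters(state["table"], config.filter)
        rep.to_tsv(outdir / "filter_report.tsv")
        state["filtered"] = filtered
        return {
            "_summary": {
                "steps": [
                    {"step": s, "before": b, "removed": r, "after": a}
                    for s, b, r, a in rep.steps
                ],
                "loci_retained": filtered.n_loci,
            }
        }

    stage("filter", filter_stage, "data")

    # -- scans -----------------------------------------------------------
    def scan_stage():
        table = state["filtered"]
        env = state["env"]
        fit, res = outliers.outflank_scan(
            table, q_threshold=config.scan_q_threshold
        )
        res.table.to_csv(outdir / "fst_scan.tsv", sep="\t", index=False)
        state["fst_outliers"] = set(res.outlier_ids)

        env_pred = env.set_index("population")[
            [c for c in ("bio12", "salinity") if c in env.columns]
        ]
        rda = outliers.rda_scan(table, env_pred.reset_index(), sd_mult=config.rda_sd_mult)
        rda.outliers.to_csv(outdir / "rda_outliers.tsv", sep="\t", index=False)

        env_of_pop = env.set_index("population")[config.env_predictor]
        per_sample = np.array(
            [env_of_pop[p] for p in table.pop_labels], dtype=float
        )
        lfa = outliers.latent_factor_assoc(table, per_sample, k=config.lfa_k)
        lfa.table.to_csv(outdir / "assoc_scan.tsv", sep="\t", index=False)

        sets = {
            "fst_scan": set(res.outlier_ids),
            "rda": set(rda.outlier_ids),
            "assoc": set(lfa.outlier_ids),
        }
        state["scan_sets"] = sets
        return {
            "_summary": {
                "envelope": {
                    "mean_fst": fit.mean_fst,
                    "df": fit.df,
                    "n_used": fit.n_used,
                },
                "outlier_counts": {k: len(v) for k, v in sets.items()},
                "overlap_all": len(
                    sets["fst_scan"] & sets["rda"] & sets["assoc"]
                ),
            }
        }

    stage("scan", scan_stage, "filter")

    # -- F_ST on the neutral set ------------------------------------------
    def fst_stage():
        table = state["filtered"]
        drop = state.get("fst_outliers", set())
        neutral_mask = ~table.loci["locus_id"].isin(drop).to_numpy()
        neutral = table.take_loci(neutral_mask)
        state["neutral"] = neutral
        theta = diffstats.global_fst(neutral)
        pw = diffstats.pairwise_fst_bootstrap(
            neutral, n_boot=config.fst_n_boot, seed=seeds["fst"]
        )
        pw.to_frame().to_csv(outdir / "pairwise_fst.tsv", sep="\t")

        pca_table = neutral
        n_pruned = 0
        if config.ld_prune_for_pca:
            pca_table, removed = filters.ld_prune(
                neutral, r2=config.filter.ld_r2, window=config.filter.ld_window
            )
            n_pruned = len(removed)
        scores, frac = diffstats.pca_genotypes(pca_table)
        np.savetxt(outdir / "pca_scores.tsv", scores, delimiter="\t")
        state["global_theta"] = theta
        return {
            "_summary": {
                "global_theta": theta,
                "mean_pairwise_theta": pw.mean_offdiag,
                "n_neutral_loci": neutral.n_loci,
                "n_ld_pruned": n_pruned,
                "pca_variance_fractions": frac[:5].tolist(),
            }
        }

    stage("fst", fst_stage, "scan")

    # -- P_ST ------------------------------------------------------------
    def pst_stage():
        traits = state.get("traits")
        if traits is None:
            return {"_summary": {"note": "no trait table supplied"}}
        theta = state["global_theta"]
        fst_ref = max(theta, -0.049)
        grid = pstfst.default_ch2_grid(config.pst_grid_n)
        trait_cols = [
            c
            for c in traits.columns
            if c not in ("sample_id", "population") + tuple(config.pst_exclude)
            and pd.api.types.is_numeric_dtype(traits[c])
        ]
        curves = {}
        for col in trait_cols:
            curve = pstfst.pst_fst_curve(
                traits[col],
                traits["population"],
                fst_ref=fst_ref,
                grid=grid,
                n_boot=config.pst_n_boot,
                seed=seeds["pst"],
            )
            curve.to_frame().to_csv(
                outdir / f"pst_curve_{col}.tsv", sep="\t", index=False
            )
            d = curve.decomposition
            curves[col] = {
                "sigma2_B": d.sigma2_B,
                "sigma2_W": d.sigma2_W,
                "ci_B": list(d.ci_B),
                "ci_W": list(d.ci_W),
                "pst_at_1": pstfst.pst_value(d.sigma2_B, d.sigma2_W, 1.0),
                "critical_ch2": curve.critical,
            }
        return {"_summary": {"fst_ref": fst_ref, "traits": curves}}

    stage("pst", pst_stage, "fst")

    # -- MMRR ------------------------------------------------------------
    def mmrr_stage():
        env = state["env"]
        neutral = state["neutral"]
        pw = diffstats.pairwise_fst_bootstrap(
            neutral, n_boot=50, seed=seeds["fst"]
        )
        dists = landscape.build_distances(env, env_columns=(config.env_predictor,))
        gen = landscape.DistanceMatrix(
            pw.populations, np.clip(pw.theta, 0, None), "genetic"
        )
        order = [gen.populations.index(p) for p in dists["geo-euclidean"].populations]
        gen = landscape.DistanceMatrix(
            dists["geo-euclidean"].populations,
            gen.values[np.ix_(order, order)],
            "genetic",
        )
        preds = {
            "geographic": dists["geo-euclidean"],
            "environmental": dists[f"env:{config.env_predictor}"],
        }
        res = landscape.mmrr(gen, preds, n_perm=config.mmrr_n_perm, seed=seeds["mmrr"])
        res.to_frame().to_csv(outdir / "mmrr.tsv", sep="\t", index=False)
        return {
            "_summary": {
                "r_squared": res.r_squared,
                "f_stat": res.f_stat,
                "f_pvalue": res.f_pvalue,
                "coefficients": dict(
                    zip(res.predictors, res.coefficients.tolist())
                ),
                "t_pvalues": dict(zip(res.predictors, res.t_pvalues.tolist())),
            }
        }

    stage("mmrr", mmrr_stage, "fst")

    # -- morpho ----------------------------------------------------------
    def morpho_stage():
        traits = state.get("traits")
        if traits is None:
            return {"_summary": {"note": "no trait table supplied"}}
        env = state["env"].set_index("population")[config.env_predictor]
        per_sample_env = traits["population"].map(env).to_numpy(dtype=float)
        fits = {}
        trait_cols = [
            c
            for c in traits.columns
            if c not in ("sample_id", "population")
            and pd.api.types.is_numeric_dtype(traits[c])
        ]
        for col in trait_cols:
            fit = morpho.fit_trait_env(traits[col], per_sample_env)
            fits[col] = {
                "degree": fit.degree,
                "coefficients": fit.coefficients,
                "p": fit.p_value,
                "r_squared": fit.r_squared,
            }
        summary: dict[str, Any] = {"fits": fits}
        pca_traits = tuple(t for t in morpho.TRAIT_COLUMNS if t in traits.columns)
        if len(pca_traits) >= 2:
            pca = morpho.trait_pca(traits, pca_traits)
            pca.loadings.to_csv(outdir / "trait_pca_loadings.tsv", sep="\t")
            summary["trait_pca_variance"] = pca.variance_fractions[:2].tolist()
        return {"_summary": summary}

    stage("morpho", morpho_stage, "fst")

    failed = [n for n, s in report["stages"].items() if s["status"] != "ok"]
    report["ok"] = not failed
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
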