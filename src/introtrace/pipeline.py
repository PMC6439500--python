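"""Pipeline orchestration: run the full analysis chain from a config file.

Stages (QC -> diversity -> differentiation -> clustering -> source search ->
hybrids -> pathway concordance) execute in dependency order on either a
genotype table read from disk or a dataset simulated from an importation
ledger.  Every artifact carries the config hash and global seed; a rerun
with an identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    filter_dataset,
    genotype_accumulation_curve,
    null_allele_frequency,
    read_genotype_table,
    write_genotype_table,
)
from .differentiation import differentiation_report, pairwise_fst, pairwise_jost_d
from .diversity import diversity_report, render_diversity_table
from .history import ImportationHistory, read_history
from .hybrids import hybrid_report
from .clustering import multi_run_plateau
from .simulate import SimulationConfig, replay_importation_history
from .source_search import SourceSearchTrace, dapc_complement, iterative_source_search

__all__ = ["PipelineConfig", "run_pipeline", "pathway_report", "stage_seed"]


_KNOWN_KEYS = {
    "genotypes", "dialect", "history", "panels", "outdir", "seed", "stages",
    "qc", "diversity", "differentiation", "clustering", "source_search",
    "hybrids", "simulate",
}
_STAGES = (
    "qc", "diversity", "differentiation", "clustering", "source_search", "hybrids",
)


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Unknown top-level keys are rejected; the full config is serialised into
    every output's metadata (as a SHA-256 hash plus the seed).
    """

    outdir: str
    seed: int = 0
    genotypes: str | None = None
    dialect: str = "native_csv"
    history: str | None = None
    panels: dict[str, list[str]] | None = None
    stages: list[str] = dataclasses.field(default_factory=lambda: list(_STAGES))
    qc: dict[str, Any] = dataclasses.field(default_factory=dict)
    diversity: dict[str, Any] = dataclasses.field(default_factory=dict)
    differentiation: dict[str, Any] = dataclasses.field(default_factory=dict)
    clustering: dict[str, Any] = dataclasses.field(default_factory=dict)
    source_search: dict[str, Any] = dataclasses.field(default_factory=dict)
    hybrids: dict[str, Any] = dataclasses.field(default_factory=dict)
    simulate: dict[str, Any] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config requires 'outdir'")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if cfg.genotypes is None and not cfg.simulate:
            raise ValueError("config needs either 'genotypes' or a 'simulate' block")
        return cfg

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (stable stage-name hash folded into the
    global seed, kept below 2**31)."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order.

    Returns a manifest mapping stage names to the artifact files written
    under ``config.outdir``.  A stage failure halts the run with an error
    naming the stage; artifacts written so far remain on disk and are
    listed in the partial manifest embedded in the raised exception.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    manifest: dict[str, Any] = {"metadata": meta, "stages": {}}
    log_lines = [f"introtrace {__version__} config={meta['config_hash']} seed={config.seed}"]

    def fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- input ------------------------------------------------------------
    history: ImportationHistory | None = None
    if config.history:
        history = read_history(config.history)
    if config.genotypes:
        ds = read_genotype_table(config.genotypes, config.dialect)
        truth = None
    else:
        sim = dict(config.simulate)
        n_sample = sim.pop("n_sample_per_pop", 25)
        growth = sim.pop("growth_generations_per_step", 10)
        burn_in = sim.pop("burn_in_generations", 200)
        if history is None:
            raise ValueError("simulate block requires a 'history' ledger")
        sim_cfg = SimulationConfig(seed=stage_seed(config.seed, "simulate"), **sim)
        ds, truth = replay_importation_history(
            history, sim_cfg, growth_generations_per_step=growth,
            burn_in_generations=burn_in, n_sample_per_pop=n_sample,
        )
        write_genotype_table(ds, outdir / "simulated_genotypes.csv")
        (outdir / "truth.json").write_text(
            json.dumps(dataclasses.asdict(truth), indent=2, sort_keys=True)
        )
        manifest["stages"]["simulate"] = ["simulated_genotypes.csv", "truth.json"]
        log_lines.append(f"simulate: {ds.n_individuals} individuals, {ds.n_loci} loci")

    # Table 1 analogue: sample bookkeeping
    counts = pd.Series(ds.populations).value_counts().reindex(ds.population_labels())
    samples = pd.DataFrame({"population": counts.index, "n": counts.values})
    samples.to_csv(outdir / "table1_samples.csv", index=False)
    manifest["stages"]["input"] = ["table1_samples.csv"]

    enabled = list(config.stages)
    if "source_search" in enabled and "clustering" not in enabled:
        log_lines.append(
            "warning: source_search requires clustering; skipping source_search"
        )
        enabled.remove("source_search")

    if "qc" in enabled:
        try:
            p = dict(config.qc)
            ds, removal_log = filter_dataset(
                ds,
                p.get("max_missing_per_locus", 0.25),
                p.get("max_missing_per_individual", 0.25),
            )
            removal_log.to_csv(outdir / "qc_removals.csv", index=False)
            null = null_allele_frequency(ds)
            pd.DataFrame(
                [{"population": k[0], "locus": k[1], "r": v} for k, v in null.r.items()]
            ).to_csv(outdir / "qc_null_alleles.csv", index=False)
            if ds.n_loci >= 2:
                genotype_accumulation_curve(
                    ds, p.get("n_resamples", 100), stage_seed(config.seed, "qc")
                ).to_csv(outdir / "qc_accumulation.csv", index=False)
            manifest["stages"]["qc"] = [
                "qc_removals.csv", "qc_null_alleles.csv", "qc_accumulation.csv"
            ]
            log_lines.append(f"qc: {len(removal_log)} removals")
        except Exception as exc:  # noqa: BLE001 - stage boundary
            fail("qc", exc)

    if "diversity" in enabled:
        try:
            p = dict(config.diversity)
            table, dmeta = diversity_report(
                ds,
                g=p.get("g"),
                n_perm=p.get("n_perm", 1000),
                n_shuffles=p.get("n_shuffles", 10000),
                seed=stage_seed(config.seed, "diversity"),
            )
            table.round(6).to_csv(outdir / "table2_diversity.csv")
            render_diversity_table(table).to_csv(outdir / "table2_diversity_rendered.csv")
            (outdir / "table2_metadata.json").write_text(
                json.dumps({**dmeta, **meta}, indent=2, sort_keys=True)
            )
            manifest["stages"]["diversity"] = [
                "table2_diversity.csv", "table2_diversity_rendered.csv",
                "table2_metadata.json",
            ]
            log_lines.append(f"diversity: g={dmeta['g']}")
        except Exception as exc:  # noqa: BLE001
            fail("diversity", exc)

    if "differentiation" in enabled:
        try:
            fst = pairwise_fst(ds)
            jd = pairwise_jost_d(ds)
            fst.values.round(6).to_csv(outdir / "table3_fst.csv")
            jd.values.round(6).to_csv(outdir / "table4_jostd.csv")
            differentiation_report(fst, jd).to_csv(
                outdir / "table34_rendered.csv", index=False
            )
            manifest["stages"]["differentiation"] = [
                "table3_fst.csv", "table4_jostd.csv", "table34_rendered.csv"
            ]
            log_lines.append("differentiation: done")
        except Exception as exc:  # noqa: BLE001
            fail("differentiation", exc)

    plateau = None
    if "clustering" in enabled:
        try:
            p = dict(config.clustering)
            plateau = multi_run_plateau(
                ds,
                k_range=tuple(p.get("k_range", (2, 4))),
                n_runs=p.get("n_runs", 50),
                n_iter=p.get("n_iter", 20),
                seed=stage_seed(config.seed, "clustering"),
            )
            record = {
                "K_estimate": plateau.K_estimate,
                "undecided_between": plateau.undecided_between,
                "plateau_lengths": {str(k): v for k, v in plateau.plateau_lengths.items()},
                "partitions": {
                    str(k): [list(r.canonical()) for r in plateau.runs[k]]
                    for k in plateau.runs
                },
                **meta,
            }
            (outdir / "clusters.json").write_text(
                json.dumps(record, indent=2, sort_keys=True)
            )
            manifest["stages"]["clustering"] = ["clusters.json"]
            log_lines.append(f"clustering: K={plateau.K_estimate}")
        except Exception as exc:  # noqa: BLE001
            fail("clustering", exc)

    traces: list[SourceSearchTrace] = []
    if "source_search" in enabled:
        try:
            p = dict(config.source_search)
            queries = p.get("queries")
            if queries is None and history is not None:
                # default: each ledger destination vs the other sampled pops
                present = set(ds.population_labels())
                queries = [
                    {
                        "novel": dest,
                        "candidates": sorted(
                            (present - {dest})
                            & ({e.source for e in history.events} | {history.native_label})
                        ),
                    }
                    for dest in sorted({e.destination for e in history.events} & present)
                ]
            for q in queries or []:
                trace = iterative_source_search(
                    q["novel"], list(q["candidates"]), ds,
                    co_allocation_threshold=p.get("threshold", 0.5),
                    seed=stage_seed(config.seed, f"source_search:{q['novel']}"),
                    n_boot=p.get("n_boot", 199),
                )
                if trace.ambiguity_flag:
                    trace = dapc_complement(
                        trace, ds, seed=stage_seed(config.seed, "dapc")
                    )
                traces.append(trace)
            (outdir / "traces.json").write_text(
                json.dumps([_trace_dict(t) for t in traces], indent=2, sort_keys=True)
            )
            manifest["stages"]["source_search"] = ["traces.json"]
            if history is not None:
                pathway_report(traces, history).to_csv(
                    outdir / "pathway_concordance.csv", index=False
                )
                manifest["stages"]["source_search"].append("pathway_concordance.csv")
            log_lines.append(f"source_search: {len(traces)} traces")
        except Exception as exc:  # noqa: BLE001
            fail("source_search", exc)

    if "hybrids" in enabled and config.panels:
        try:
            hybrid_report(ds, config.panels).to_csv(
                outdir / "hybrid_calls.csv", index=False
            )
            manifest["stages"]["hybrids"] = ["hybrid_calls.csv"]
            log_lines.append("hybrids: done")
        except Exception as exc:  # noqa: BLE001
            fail("hybrids", exc)

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _trace_dict(t: SourceSearchTrace) -> dict[str, Any]:
    return {
        "novel": t.novel,
        "outcome": t.outcome,
        "final_sources": t.final_sources,
        "ambiguity": t.ambiguity_flag,
        "threshold": t.threshold,
        "rounds": [
            {
                "candidates": r.candidates,
                "co_allocation": r.co_allocation,
                "discarded": r.discarded,
                "rule": r.rule,
            }
            for r in t.rounds
        ],
        "significance": {
            s: {"mean_llod": v[0], "p": v[1]} for s, v in t.significance.items()
        },
        "dapc_ranking": t.dapc_ranking,
    }


def pathway_report(
    traces: list[SourceSearchTrace], history: ImportationHistory
) -> pd.DataFrame:
    """Concordance of inferred sources with the documented ledger.

    Per trace: the documented source(s) of the novel population, the
    inferred final source(s), and a match status — ``concordant`` (sets
    agree), ``clarified`` (several documented sources narrowed to a subset),
    ``discordant`` (no overlap), ``untested-source`` (search discarded all
    candidates), or ``unmatched`` (population absent from the ledger).
    """
    rows = []
    documented_by_pop = {
        dest: sorted({e.source for e in history.events_into(dest)})
        for dest in {e.destination for e in history.events}
    }
    for t in traces:
        documented = documented_by_pop.get(t.novel)
        inferred = sorted(t.final_sources)
        if documented is None:
            status = "unmatched"
            documented = []
        elif t.outcome == "untested_source":
            status = "untested-source"
        elif set(inferred) == set(documented):
            status = "concordant"
        elif inferred and set(inferred) <= set(documented):
            status = "clarified"
        elif inferred and set(inferred) & set(documented):
            status = "clarified"
        else:
            status = "discordant"
        rows.append(
            {
                "population": t.novel,
                "documented_sources": ";".join(documented),
                "inferred_sources": ";".join(inferred),
                "status": status,
            }
        )
    return pd.DataFrame(rows, columns=["population", "documented_sources", "inferred_sources", "status"])
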