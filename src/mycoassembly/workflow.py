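"""Orchestration: run the full analysis from a config, stage by stage.

Stage order mirrors the analysis: taxonomy filter -> alpha diversity +
Kruskal-Wallis/Dunn -> beta diversity + PERMANOVA/PERMDISP (with
pairwise follow-ups) -> per-ocean distance decay (Mantel, correlogram,
MRM, zero-distance-masked variant) -> rarefaction -> abundance-occupancy
-> core identification -> neutral fit + deviation classification ->
core/deviation/differential-abundance summary join.

Each completed stage leaves a ``<stage>.done`` marker in the output
directory; re-running skips completed stages, and a failure aborts with
the stage name while retaining partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_neutral import (
    abundance_occupancy,
    classify_deviation,
    core_by_contribution,
    fit_sloan,
    rank_asvs,
    summarize_core,
)
from .data_io import (
    CountTable,
    filter_by_taxonomy,
    rarefy,
    read_count_table,
    read_differential_abundance,
    read_metadata,
    read_taxonomy,
    write_count_table,
)
from .distance_decay import geo_matrix, mantel, mantel_correlogram, mantel_masked, mrm
from .diversity import alpha_diversity, beta_distance, write_distance_matrix
from .multivariate import (
    dunn_posthoc,
    kruskal_wallis,
    pairwise_permanova,
    permanova,
    permdisp,
    tukey_hsd,
)

logger = logging.getLogger("mycoassembly")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """All pipeline knobs in one structured record.

    Defaults follow the analysis conventions: rarefaction depth 1,000,
    9,999 permutations, 10% core percent-increase threshold, alpha 0.05.
    """

    counts: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    da_table: str | None = None
    outdir: str = "results"
    rarefaction_depth: int = 1000
    n_permutations: int = 9999
    core_threshold: float = 0.10
    alpha: float = 0.05
    seed: int = 0
    metrics: tuple[str, ...] = ("bray_curtis", "hellinger", "aitchison")
    group_by: tuple[str, ...] = ("sample_type", "site_code", "ocean")
    clr_pseudocount: float = 1.0

    def __post_init__(self):
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        if self.n_permutations < 99:
            raise ValueError("use at least 99 permutations")
        if not 0 < self.core_threshold < 1:
            raise ValueError("core threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("metrics", "group_by"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(outdir: Path, name: str):
    """Decorator-free stage guard: returns True if already done."""
    marker = outdir / f"{name}.done"
    return marker


def run_pipeline(
    config: PipelineConfig,
    table: CountTable | None = None,
    meta: pd.DataFrame | None = None,
    tax: pd.DataFrame | None = None,
    da: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis; inputs may be given in memory or read
    from the paths in ``config``.  Returns a manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": {
            "mycoassembly": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    if table is None:
        if config.counts is None:
            raise PipelineError("stage load: no count table given")
        table = read_count_table(config.counts)
    if meta is None:
        if config.metadata is None:
            raise PipelineError("stage load: no metadata given")
        meta = read_metadata(config.metadata)
    if tax is None and config.taxonomy is not None:
        tax = read_taxonomy(config.taxonomy)
    if da is None and config.da_table is not None:
        da = read_differential_abundance(config.da_table)

    def run(name, fn):
        marker = outdir / f"{name}.done"
        if marker.exists():
            logger.info("stage %s: already complete, skipping", name)
            manifest["stages"][name] = "skipped (done)"
            return None
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage {name}: {exc}") from exc
        marker.write_text("done\n")
        manifest["stages"][name] = "complete"
        return result

    state: dict = {"table": table}

    # -- taxonomy filter ------------------------------------------------
    def stage_filter():
        if tax is None:
            logger.info("no taxonomy supplied; skipping domain filter")
            state["filtered"] = state["table"]
            return
        filtered, report = filter_by_taxonomy(state["table"], tax, keep="Fungi")
        for sid in report.dropped_samples:
            logger.info("dropped sample %s: %s", sid, report.rule)
        write_count_table(filtered, outdir / "filtered_counts.tsv")
        (outdir / "filter_report.json").write_text(
            json.dumps(
                {
                    "rule": report.rule,
                    "dropped_samples": report.dropped_samples,
                    "n_dropped_asvs": len(report.dropped_asvs),
                }
            )
        )
        state["filtered"] = filtered

    run("filter", stage_filter)
    if "filtered" not in state:  # stage skipped on resume
        f = outdir / "filtered_counts.tsv"
        state["filtered"] = read_count_table(f) if f.exists() else state["table"]
    table = state["filtered"]
    meta = meta.loc[table.sample_ids]
    types = meta["sample_type"]

    # -- alpha diversity -------------------------------------------------
    def stage_alpha():
        shannon = alpha_diversity(table)
        shannon.to_frame().assign(sample_type=types).to_csv(
            outdir / "alpha_diversity.tsv", sep="\t"
        )
        rows = []
        kw = kruskal_wallis(
            shannon.to_numpy(), types.to_numpy(), config.n_permutations,
            seed=rng.integers(2**31),
        )
        rows.append(("sample_type", kw.statistic, kw.p_value))
        if kw.p_value < config.alpha:
            dunn_posthoc(shannon.to_numpy(), types.to_numpy()).to_csv(
                outdir / "alpha_dunn_sample_type.tsv", sep="\t", index=False
            )
        for group in ("site_code", "ocean"):
            for stype in sorted(types.unique()):
                mask = (types == stype).to_numpy()
                labels = meta.loc[mask, group]
                if labels.nunique() < 2:
                    continue
                kw = kruskal_wallis(
                    shannon.to_numpy()[mask], labels.to_numpy(),
                    config.n_permutations, seed=rng.integers(2**31),
                )
                rows.append((f"{group}|{stype}", kw.statistic, kw.p_value))
        pd.DataFrame(rows, columns=["comparison", "H", "p_value"]).to_csv(
            outdir / "alpha_tests.tsv", sep="\t", index=False
        )

    run("alpha", stage_alpha)

    # -- beta diversity ---------------------------------------------------
    def stage_beta():
        rows = []
        for metric in config.metrics:
            dm = beta_distance(table, metric, pseudocount=config.clr_pseudocount)
            write_distance_matrix(dm, outdir / f"distance_{metric}.tsv")
            for group in config.group_by:
                labels = meta[group].to_numpy()
                if len(np.unique(labels)) < 2:
                    continue
                res = permanova(dm, labels, config.n_permutations,
                                seed=rng.integers(2**31))
                rows.append((metric, group, "permanova", res.statistic, res.p_value))
                disp, dists = permdisp(dm, labels, config.n_permutations,
                                       seed=rng.integers(2**31))
                rows.append((metric, group, "permdisp", disp.statistic, disp.p_value))
                if disp.p_value < config.alpha and len(np.unique(labels)) > 2:
                    tukey_hsd(dists.to_numpy(), labels).to_csv(
                        outdir / f"tukey_{metric}_{group}.tsv", sep="\t", index=False
                    )
            pairwise_permanova(
                dm, types.to_numpy(), config.n_permutations,
                seed=rng.integers(2**31),
            ).to_csv(outdir / f"pairwise_permanova_{metric}.tsv", sep="\t", index=False)
        pd.DataFrame(
            rows, columns=["metric", "grouping", "test", "statistic", "p_value"]
        ).to_csv(outdir / "beta_tests.tsv", sep="\t", index=False)

    run("beta", stage_beta)

    # -- distance decay ---------------------------------------------------
    def stage_decay():
        rows = []
        for ocean in sorted(meta["ocean"].unique()):
            for stype in sorted(types.unique()):
                mask = ((meta["ocean"] == ocean) & (types == stype)).to_numpy()
                if mask.sum() < 8 or meta.loc[mask, "site_code"].nunique() < 3:
                    continue
                sub = table.select_samples(np.asarray(table.sample_ids)[mask])
                sub = sub.drop_empty_asvs()
                geo = geo_matrix(meta.loc[mask])
                for metric in ("bray_curtis", "hellinger"):
                    dm = beta_distance(sub, metric)
                    man = mantel(dm, geo, config.n_permutations,
                                 seed=rng.integers(2**31))
                    rows.append((ocean, stype, metric, "mantel",
                                 man.statistic, man.p_value))
                    masked = mantel_masked(dm, geo, config.n_permutations,
                                           seed=rng.integers(2**31))
                    rows.append((ocean, stype, metric, "mantel_nonzero",
                                 masked.statistic, masked.p_value))
                    reg = mrm(dm, geo, config.n_permutations,
                              seed=rng.integers(2**31), names=["geo_km"])
                    rows.append((ocean, stype, metric, "mrm_slope",
                                 reg.coefficients["geo_km"],
                                 reg.coef_p_values["geo_km"]))
                    cg = mantel_correlogram(dm, geo, n_perm=config.n_permutations,
                                            seed=rng.integers(2**31))
                    cg.as_frame().to_csv(
                        outdir / f"correlogram_{ocean}_{stype}_{metric}.tsv",
                        sep="\t", index=False,
                    )
        pd.DataFrame(
            rows,
            columns=["ocean", "sample_type", "metric", "test", "statistic", "p_value"],
        ).to_csv(outdir / "decay_tests.tsv", sep="\t", index=False)

    run("decay", stage_decay)

    # -- rarefaction + core + neutral fit ---------------------------------
    def stage_core_neutral():
        cores, dev_labels, fit_summary = {}, {}, {}
        for stype in sorted(types.unique()):
            mask = (types == stype).to_numpy()
            sub = table.select_samples(np.asarray(table.sample_ids)[mask])
            rare, report = rarefy(sub, config.rarefaction_depth,
                                  seed=rng.integers(2**31))
            for sid in report.dropped_samples:
                logger.info("dropped sample %s: %s", sid, report.rule)
            if rare.shape[0] < 10:
                logger.warning("sample type %s: too few samples after "
                               "rarefaction; skipping", stype)
                continue
            rare = rare.drop_empty_asvs()
            write_count_table(rare, outdir / f"rarefied_{stype}.tsv")
            ao = abundance_occupancy(rare, meta)
            ranking = rank_asvs(ao)
            core = core_by_contribution(rare, ranking, config.core_threshold)
            core.as_frame().to_csv(outdir / f"core_{stype}.tsv", sep="\t", index=False)
            fit = fit_sloan(ao)
            labels = classify_deviation(ao, fit)
            fit.frame.assign(deviation=labels).to_csv(
                outdir / f"neutral_{stype}.tsv", sep="\t"
            )
            fit_summary[stype] = {
                "m": fit.m, "N": fit.N, "d": fit.d, "r_squared": fit.r_squared,
                "n_samples": fit.n_samples, "n_core": len(core.core_set),
            }
            cores[stype] = core
            dev_labels[stype] = labels
        (outdir / "neutral_fit_summary.json").write_text(
            json.dumps(fit_summary, indent=2)
        )
        if da is not None and cores:
            summary = summarize_core(cores, dev_labels, da, tax, config.alpha)
            summary.to_csv(outdir / "core_summary.tsv", sep="\t", index=False)

    run("core_neutral", stage_core_neutral)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
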