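"""End-to-end pipeline: simulate (optional) -> QC -> population / twins ->
heritability, with every artifact written under one output directory and a
machine-readable manifest of SHA-256 checksums.

With a fixed seed and ``timestamped=False`` two runs produce byte-identical
artifacts and therefore identical manifest checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as tio
from .datatypes import MethylationMatrix
from .heritability import distance_vs_s, heritability_estimates, shared_environment_table
from .population import anova_pc1, cpg_correlation_matrix, group_summary, pca_pc1
from .qc import QCConfig, run_qc
from .simulate import SimConfig, simulate_population_cohort, simulate_twin_cohort
from .twins import age_class_summary, age_trend, compute_pair_statistics, threshold_test

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``simulate`` is set (synthetic cohorts are generated) or the
    three input paths point at existing TSVs.  Stages can be toggled; the
    heritability stage needs the twins stage's pair statistics.
    """

    out_dir: str | Path = "twinmeth_run"
    seed: int = 0
    timestamped: bool = True
    simulate: SimConfig | None = None
    matrix_path: str | Path | None = None
    metadata_path: str | Path | None = None
    pairs_path: str | Path | None = None
    pop_matrix_path: str | Path | None = None
    pop_metadata_path: str | Path | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    run_population: bool = True
    run_twins: bool = True
    run_heritability: bool = True
    threshold_age: float = 60.0
    s_threshold: float = 35.0
    falconer_summary: str = "mean"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate is None:
            if self.run_twins and (self.matrix_path is None or self.pairs_path is None):
                raise ValueError(
                    "twins stage enabled but no simulation config and no "
                    "matrix_path/pairs_path given"
                )
            if self.run_population and (
                self.pop_matrix_path is None or self.pop_metadata_path is None
            ):
                raise ValueError(
                    "population stage enabled but no simulation config and no "
                    "pop_matrix_path/pop_metadata_path given"
                )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {unknown}")
        if "simulate" in d and d["simulate"] is not None and not isinstance(d["simulate"], SimConfig):
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        if "qc" in d and not isinstance(d["qc"], QCConfig):
            qc = dict(d["qc"])
            bad = sorted(set(qc) - set(QCConfig.__dataclass_fields__))
            if bad:
                raise ValueError(f"unknown QCConfig keys: {bad}")
            if "control_units" in qc:
                qc["control_units"] = tuple(qc["control_units"])
            d["qc"] = QCConfig(**qc)
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the configured stages and return the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    if config.timestamped:
        out = out / time.strftime("run-%Y%m%d-%H%M%S")
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, **kwargs) -> None:
        p = out / name
        df.to_csv(p, sep="\t", na_rep=tio.MISSING_TOKEN, **kwargs)
        artifacts.append(p)

    def save_json(obj: Any, name: str) -> None:
        p = out / name
        p.write_text(json.dumps(obj, indent=2, default=str) + "\n")
        artifacts.append(p)

    # ---- inputs -------------------------------------------------------
    @_stage("simulate")
    def _inputs():
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            matrix, meta, pairs = simulate_twin_cohort(sim)
            pop_matrix, pop_meta = simulate_population_cohort(
                dataclasses.replace(sim, seed=config.seed + 1)
            )
            tio.write_matrix(matrix, out / "twin_matrix.tsv")
            tio.write_metadata(meta, out / "twin_metadata.tsv")
            tio.write_pairs(pairs, out / "twin_pairs.tsv")
            tio.write_matrix(pop_matrix, out / "population_matrix.tsv")
            tio.write_metadata(pop_meta, out / "population_metadata.tsv")
            artifacts.extend(out / n for n in (
                "twin_matrix.tsv", "twin_metadata.tsv", "twin_pairs.tsv",
                "population_matrix.tsv", "population_metadata.tsv"))
            return matrix, meta, pairs, pop_matrix, pop_meta
        matrix = tio.read_matrix(config.matrix_path) if config.matrix_path else None
        meta = tio.read_metadata(config.metadata_path) if config.metadata_path else None
        pairs = tio.read_pairs(config.pairs_path) if config.pairs_path else None
        pop_matrix = tio.read_matrix(config.pop_matrix_path) if config.pop_matrix_path else None
        pop_meta = tio.read_metadata(config.pop_metadata_path) if config.pop_metadata_path else None
        return matrix, meta, pairs, pop_matrix, pop_meta

    matrix, meta, pairs, pop_matrix, pop_meta = _inputs()
    results: dict[str, Any] = {}

    # ---- qc -----------------------------------------------------------
    @_stage("qc")
    def _qc(m: MethylationMatrix, tag: str) -> MethylationMatrix:
        clean, report = run_qc(m, config.qc)
        (out / f"qc_report_{tag}.json").write_text(report.to_json() + "\n")
        artifacts.append(out / f"qc_report_{tag}.json")
        results[f"qc_{tag}"] = {
            "n_samples_after": report.n_samples_after,
            "n_units_after": report.n_units_after,
        }
        return clean

    if matrix is not None:
        matrix = _qc(matrix, "twins")
    if pop_matrix is not None:
        pop_matrix = _qc(pop_matrix, "population")

    # ---- population ---------------------------------------------------
    if config.run_population and pop_matrix is not None:
        @_stage("population")
        def _population():
            groups = pop_meta.set_index("sample_id")["group"]
            groups = groups.loc[[s for s in pop_matrix.sample_ids]]
            save_df(group_summary(pop_matrix, groups), "population_group_summary.tsv",
                    index=False)
            save_df(cpg_correlation_matrix(pop_matrix), "population_cpg_correlation.tsv")
            per_amp = {}
            for amp in pop_matrix.amplicons:
                pca = pca_pc1(pop_matrix, amp)
                anova = anova_pc1(pca.scores, groups)
                per_amp[amp] = {
                    "variance_explained_pc1": pca.variance_explained_pc1,
                    "F": anova.f_statistic,
                    "p": anova.p_value,
                }
            save_json(per_amp, "population_pca_anova.json")
            results["population"] = per_amp
        _population()

    # ---- twins --------------------------------------------------------
    pair_stats = None
    if config.run_twins and matrix is not None:
        @_stage("twins")
        def _twins():
            nonlocal pair_stats
            pair_stats = compute_pair_statistics(matrix, pairs)
            save_df(pair_stats, "twin_pair_statistics.tsv", index=False)
            ages = meta.set_index("sample_id")["age"]
            save_df(age_class_summary(matrix, ages), "twin_age_class_summary.tsv",
                    index=False)
            mz = pair_stats[pair_stats["zygosity"] == "MZ"]
            trends: dict[str, Any] = {}
            for amp in matrix.amplicons:
                trends[amp] = {}
                for statistic in ("correlation", "distance"):
                    entry: dict[str, Any] = {}
                    try:
                        tr = age_trend(mz, amp, statistic)
                        entry["spearman_rho"] = tr.spearman_rho
                        entry["n_pairs"] = tr.n_pairs
                    except ValueError as exc:
                        entry["trend_undefined"] = str(exc)
                    try:
                        tt = threshold_test(mz, amp, statistic, config.threshold_age)
                        entry["t"] = tt.t_statistic
                        entry["p"] = tt.p_value
                        entry["n_young"] = tt.n_young
                        entry["n_old"] = tt.n_old
                    except ValueError as exc:
                        entry["threshold_test_undefined"] = str(exc)
                    trends[amp][statistic] = entry
            save_json(trends, "twin_trend_threshold.json")
            results["twins"] = trends
        _twins()

    # ---- heritability -------------------------------------------------
    if config.run_heritability and pair_stats is not None:
        @_stage("heritability")
        def _heritability():
            estimates = heritability_estimates(pair_stats, config.falconer_summary)
            payload = {
                e.amplicon: {
                    "r_mz_mean": e.r_mz_mean, "r_mz_median": e.r_mz_median,
                    "r_dz_mean": e.r_dz_mean, "r_dz_median": e.r_dz_median,
                    "h2": e.h2, "n_mz": e.n_mz_pairs, "n_dz": e.n_dz_pairs,
                }
                for e in estimates
            }
            save_json(payload, "heritability.json")
            results["heritability"] = payload
            frames = []
            for amp in pair_stats["amplicon"].unique():
                rec = shared_environment_table(pair_stats, amp)
                rec.insert(0, "amplicon", amp)
                frames.append(rec)
                dvs = distance_vs_s(rec, amp, config.s_threshold)
                results.setdefault("distance_vs_s", {})[amp] = {
                    "spearman_rho": dvs.spearman_rho,
                    "n_discordant_cohabiters": len(dvs.discordant_cohabiters),
                }
            save_df(pd.concat(frames, ignore_index=True),
                    "shared_environment.tsv", index=False)
            save_json(results["distance_vs_s"], "distance_vs_s.json")
        _heritability()

    manifest = {
        "seed": config.seed,
        "out_dir": str(out),
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
        "results": results,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
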