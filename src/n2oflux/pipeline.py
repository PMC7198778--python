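"""End-to-end orchestration: simulate -> fluxes -> partition -> Q10 ->
community -> qPCR -> report.

Configuration is a plain dataclass (optionally loaded from YAML); every stage
reads CSVs written by the previous one, so a real study laid out in the same
CSV formats can replace the simulated inputs.  A manifest records seeds and
parameters, and its hash is stable under rerun with the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import community as comm
from . import fluxcalc, partition, qpcr, synth, tempsens
from .design import CAMPAIGN_DAYS

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("n2oflux")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    outdir: str = "n2oflux_run"
    simulate: bool = True
    scenario: str = "paper-default"        # paper-default | null
    seed: int = 1
    gas_csv: str | None = None             # used when simulate=False
    peaks_csv: dict = field(default_factory=dict)   # gene -> path
    community_meta_csv: str | None = None
    standards_csv: str | None = None
    qpcr_csv: str | None = None
    dry_mass_g: float = 18.0
    bootstrap_B: int = 1000
    mc_sd: float | str = "auto"
    alpha: float = 0.05
    permutations: int = 999
    elution_volume_ul: float = 50.0
    day0_rule: str = "constant"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - named-stage contract
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    if cfg.scenario == "paper-default":
        study = synth.generate_study(synth.paper_default_scenario(), seed=cfg.seed)
    elif cfg.scenario == "null":
        study = synth.generate_null_study(seed=cfg.seed)
    else:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    return study.write_csvs(outdir / "sim")


@_stage("fluxes")
def _run_fluxes(cfg: RunConfig, gas_path: Path, outdir: Path) -> pd.DataFrame:
    if not gas_path.exists():
        raise FileNotFoundError(f"missing gas table {gas_path}")
    gas = pd.read_csv(gas_path)
    rates = fluxcalc.rates_from_gas_table(gas, dry_mass_g=cfg.dry_mass_g)
    rates.to_csv(outdir / "rates.csv", index=False)
    return rates


@_stage("partition")
def _run_partition(cfg: RunConfig, rates: pd.DataFrame, outdir: Path):
    campaign = rates[rates["day"].isin(CAMPAIGN_DAYS)]
    campaign = campaign.groupby(
        ["fertilization", "temperature_C", "replicate", "day"]
    ).filter(lambda g: set(g["c2h2_level"]) >= {"P0", "P10", "KP10"})
    process = partition.partition_rates_table(campaign)
    process.to_csv(outdir / "process_rates.csv", index=False)
    boot = partition.bootstrap_infer(
        campaign, statistic="gross_consumption", B=cfg.bootstrap_B,
        mc_sd=cfg.mc_sd, seed=cfg.seed, alpha=cfg.alpha,
    )
    boot.cells.to_csv(outdir / "bootstrap_cells.csv", index=False)
    boot.pairwise.to_csv(outdir / "bootstrap_pairwise.csv", index=False)
    return process


@_stage("q10")
def _run_q10(cfg: RunConfig, rates: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    net = rates[rates["c2h2_level"] == "P0"]
    rows = []
    series_by_fert: dict[str, list] = {}
    for fert, sub in net.groupby("fertilization"):
        rep_series = []
        for rep, reps in sub.groupby("replicate"):
            pts = []
            for temp, cell in reps.groupby("temperature_C"):
                cell = cell.sort_values("day")
                cum = fluxcalc.cumulative_emission(
                    list(zip(cell["day"], cell["rate_ngN_g_d"])),
                    day0_rule=cfg.day0_rule,
                )
                pts.append((float(temp), cum))
            rep_series.append(pts)
        series_by_fert[fert] = rep_series
        fit = tempsens.fit_replicate_q10(rep_series)
        rows.append({
            "fertilization": fert, "q10": fit.q10, "beta": fit.beta,
            "alpha": fit.alpha, "r_squared": fit.r_squared, "mode": fit.method,
        })
    q10 = pd.DataFrame(rows)
    q10.to_csv(outdir / "q10.csv", index=False)

    comp_rows = []
    ferts = sorted(series_by_fert)
    for i in range(len(ferts)):
        for j in range(i + 1, len(ferts)):
            c = tempsens.compare_q10(series_by_fert[ferts[i]],
                                     series_by_fert[ferts[j]], seed=cfg.seed)
            comp_rows.append({
                "fert_A": ferts[i], "fert_B": ferts[j],
                "q10_A": c.q10_a, "q10_B": c.q10_b, "difference": c.difference,
                "ci_lo": c.ci_lo, "ci_hi": c.ci_hi, "p": c.p,
            })
    pd.DataFrame(comp_rows).to_csv(outdir / "q10_comparisons.csv", index=False)
    return q10


@_stage("community")
def _run_community(cfg: RunConfig, peak_paths: dict, meta_path: Path,
                   process: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path)
    results = []
    for gene, path in sorted(peak_paths.items()):
        frame = pd.read_csv(path)
        tables = [
            comm.PeakTable(sid, list(zip(sub["fragment_bp"], sub["height"])))
            for sid, sub in frame.groupby("sample_id", sort=True)
        ]
        matrix = comm.process_peaks(tables, metadata=meta)
        dist = comm.bray_curtis_matrix(matrix.abundances)
        dist.to_csv(outdir / f"distances_{gene}.csv")
        matrix.abundances.to_csv(outdir / f"community_{gene}.csv")
        sub_meta = meta.set_index("sample_id").loc[dist.index]
        incubated = sub_meta["day"] > 0
        d_inc = dist.loc[incubated.values, incubated.values]
        factors = sub_meta.loc[incubated.values, ["day", "fertilization",
                                                  "temperature_C"]]
        res = comm.permanova(d_inc, factors, permutations=cfg.permutations,
                             seed=cfg.seed)
        res.insert(0, "gene", gene)
        results.append(res)
    table = pd.concat(results, ignore_index=True)
    table.to_csv(outdir / "permanova.csv", index=False)
    return table


@_stage("qpcr")
def _run_qpcr(cfg: RunConfig, standards_path: Path, qpcr_path: Path,
              outdir: Path) -> pd.DataFrame:
    standards = pd.read_csv(standards_path)
    samples = pd.read_csv(qpcr_path)
    rows = []
    for gene, std in standards.groupby("gene"):
        curve = qpcr.fit_standard_curve(
            list(zip(std["log10_copies"], std["cq"])), gene=gene
        )
        sub = samples[samples["gene"] == gene]
        for sid, reps in sub.groupby("sample_id"):
            est = qpcr.quantify_replicates(
                reps["cq"].tolist(), curve,
                elution_volume_ul=cfg.elution_volume_ul, sample_id=sid,
            )
            rows.append({
                "sample_id": sid, "gene": gene,
                "copies_per_g": est.copies_per_g, "cv": est.cv,
                "efficiency": curve.efficiency, "extrapolated": est.extrapolated,
            })
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "abundance.csv", index=False)
    return table


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return a report bundle (dict).

    Raises :class:`PipelineError` naming the failing stage; outputs of
    completed stages are retained in ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []

    if cfg.simulate:
        sim_paths = _run_simulate(cfg, outdir)
        gas_path = sim_paths["gas.csv"]
        peak_paths = {g: sim_paths[f"peaks_{g}.csv"] for g in synth.GENES}
        meta_path = sim_paths["community_meta.csv"]
        standards_path = sim_paths["standards.csv"]
        qpcr_path = sim_paths["qpcr.csv"]
    else:
        if not cfg.gas_csv:
            raise PipelineError("stage 'fluxes' failed: no gas_csv configured")
        gas_path = Path(cfg.gas_csv)
        peak_paths = {g: Path(p) for g, p in cfg.peaks_csv.items()}
        meta_path = Path(cfg.community_meta_csv) if cfg.community_meta_csv else None
        standards_path = Path(cfg.standards_csv) if cfg.standards_csv else None
        qpcr_path = Path(cfg.qpcr_csv) if cfg.qpcr_csv else None

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        rates = _run_fluxes(cfg, gas_path, outdir)
        process = _run_partition(cfg, rates, outdir)
        q10 = _run_q10(cfg, rates, outdir)
        permanova_table = (
            _run_community(cfg, peak_paths, meta_path, process, outdir)
            if peak_paths and meta_path is not None else None
        )
        abundance = (
            _run_qpcr(cfg, standards_path, qpcr_path, outdir)
            if standards_path is not None and qpcr_path is not None else None
        )
        caught = sorted({str(w.message) for w in wlist})

    ratios = process["ratio_con_pro"].dropna()
    report = {
        "config": asdict(cfg),
        "q10": q10.to_dict("records"),
        "process_rates_file": str(outdir / "process_rates.csv"),
        "ratio_summary": {
            "mean": float(ratios.mean()), "min": float(ratios.min()),
            "max": float(ratios.max()), "n_cells": int(len(ratios)),
        },
        "permanova": permanova_table.to_dict("records")
        if permanova_table is not None else None,
        "n_abundance_samples": None if abundance is None else int(len(abundance)),
        "warnings": caught,
    }
    manifest = {
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "outputs": sorted(p.name for p in outdir.rglob("*.csv")),
    }
    manifest_json = json.dumps(manifest, sort_keys=True, default=str)
    manifest["hash"] = hashlib.sha256(manifest_json.encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    report["manifest_hash"] = manifest["hash"]
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
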