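"""End-to-end orchestration of the analysis chain.

``run_pipeline`` executes every stage on one workspace directory — by
default on synthetic inputs it generates itself — and writes the tables,
series, statistical report and a provenance record.  Each stage failure is
re-raised labelled with the stage name so the CLI can report it and exit
non-zero.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, climatology, icepheno, io, mld, stats, synth
from .config import PipelineConfig
from .errors import WapmeltError
from .watermass import EndMemberSet, decompose_table

log = logging.getLogger("wapmelt")


class StageError(WapmeltError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _endmembers(config: PipelineConfig) -> EndMemberSet:
    if config.endmembers is None:
        raise WapmeltError(
            "no end-members configured: decomposition refuses to run "
            "without explicit (salinity, d18o) end-member values")
    e = config.endmembers
    return EndMemberSet(e.s_sim, e.s_met, e.s_ow,
                        e.d18o_sim, e.d18o_met, e.d18o_ow)


def simulate_inputs(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Generate every synthetic input the pipeline reads, plus truths."""
    outdir.mkdir(parents=True, exist_ok=True)
    sc = config.synth
    seed = config.seed
    paths: dict[str, Path] = {}

    em = _endmembers(config) if config.endmembers else synth.EXAMPLE_ENDMEMBERS
    rng = synth.substream(seed, "pipeline-fractions")
    triplets = synth.random_fraction_triplets(sc.n_mixture_samples, rng, low=0.0)
    samples, truth = synth.make_mixture_samples(
        em, triplets, noise_sd=sc.mixture_noise_sd, seed=seed)
    paths["samples"] = outdir / "samples.csv"
    samples.to_csv(paths["samples"], index=False)
    truth.to_csv(outdir / "samples_truth.csv", index=False)

    series, sic_truth = synth.make_sic_series(
        sc.sic_anchor_year, sc.sic_advance_jd, sc.sic_retreat_jd,
        plateau=sc.sic_plateau, noise_sd=sc.sic_noise_sd,
        cadence=sc.sic_cadence, seed=seed)
    paths["sic"] = outdir / "sic.csv"
    io.write_sic_csv(series, paths["sic"])
    io.write_report_json(sic_truth, outdir / "sic_truth.json")

    depth, dens, prof_truth = synth.make_profile(
        sc.mld_m, sc.mld_step_kgm3, seed=seed)
    paths["profile"] = outdir / "profile.csv"
    pd.DataFrame({"depth_m": depth, "density_kgm3": dens}).to_csv(
        paths["profile"], index=False)
    io.write_report_json(prof_truth, outdir / "profile_truth.json")

    fields, truth = synth.make_coupled_fields(
        rho_target=sc.rho_target, start=sc.coupled_start, end=sc.coupled_end,
        seed=seed)
    for name, da in fields.items():
        p = outdir / f"{name}.nc"
        io.write_gridded(da, p, var=name)
        paths[name] = p
    io.write_report_json(
        {"rho_target": truth["rho_target"],
         "n_observed_days": truth["n_observed_days"]},
        outdir / "coupled_truth.json")
    return paths


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the report dict (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {k: Path(v) for k, v in config.paths.items()}
    report: dict = {}

    if not inputs:
        stage = "simulate"
        log.info("no input paths configured; generating synthetic inputs")
        try:
            inputs = simulate_inputs(config, outdir / "inputs")
        except Exception as e:
            raise StageError(stage, e) from e

    try:
        stage = "decompose"
        samples = io.read_samples_csv(inputs["samples"])
        em = _endmembers(config) if config.endmembers \
            else synth.EXAMPLE_ENDMEMBERS
        fr = decompose_table(samples, em)
        io.write_fractions_csv(samples, fr, outdir / "fractions.csv")
        report["decompose"] = {
            "n_samples": int(len(fr)),
            "n_failed": int((fr["error"] != "").sum()),
            "n_out_of_range": int((fr["out_of_range"] == True).sum()),  # noqa: E712
        }

        stage = "ice-index"
        series = io.read_sic_csv(inputs["sic"])
        year = int(pd.Timestamp(series.dates[0]).year)
        idx = icepheno.season_indices(series, year,
                                      config.sic_threshold_pct,
                                      config.sic_persistence_days)
        pd.DataFrame([idx.__dict__]).to_csv(outdir / "ice_indices.csv",
                                            index=False)
        report["ice_index"] = {"year": idx.year, "advance_jd": idx.advance_jd,
                               "retreat_jd": idx.retreat_jd,
                               "duration_days": idx.duration_days}

        stage = "mld"
        depth, dens = io.read_profile_csv(inputs["profile"])
        est = mld.estimate_mld(depth, dens, qi_threshold=config.qi_threshold)
        pd.DataFrame([{"profile_id": Path(inputs["profile"]).stem,
                       "mld_m": est.mld_m, "qi": est.qi,
                       "category": est.category}]).to_csv(
            outdir / "mld.csv", index=False)
        report["mld"] = {"mld_m": est.mld_m, "qi": est.qi,
                         "category": est.category}

        stage = "climatology"
        roi = climatology.RegionOfInterest(config.roi_vertices)
        regional = {}
        for name in ("chla", "sgmw", "sst", "sat"):
            if name not in inputs:
                continue
            field = io.read_gridded(inputs[name])
            rs = climatology.regional_mean(field, roi)
            io.write_regional_series_csv(rs, name,
                                         outdir / f"regional_{name}.csv")
            regional[name] = rs
        report["climatology"] = {
            name: {"n_days": int(rs["value"].notna().sum()),
                   "mean": float(rs["value"].mean())}
            for name, rs in regional.items()}

        stage = "compare"
        comparisons = {}
        for name in ("chla", "sgmw"):
            if name in regional:
                comp = stats.compare_periods(regional[name],
                                             config.period_split)
                comparisons[name] = comp.to_dict()
        corr = None
        if "chla" in regional and "sgmw" in regional:
            corr = stats.correlate(regional["sgmw"]["value"],
                                   regional["chla"]["value"],
                                   transform=config.chla_transform)
            report["correlation"] = {"r": corr.r, "p": corr.p, "n": corr.n,
                                     "transform": corr.transform}
        report["comparisons"] = comparisons
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e

    report["provenance"] = {
        "wapmelt_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    io.write_report_json(report, outdir / "report.json")
    return report
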