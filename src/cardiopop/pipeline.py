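"""End-to-end study orchestration.

``run_study`` executes the whole pipeline from one :class:`StudyConfig`:
synthetic calibration envelopes -> Latin-Hypercube sampling -> population
evaluation + calibration (checkpointed, the expensive stage) -> alternans
classification -> calcium-balance analysis of the alternans models ->
statistics (partial correlations, normal-vs-alternans group comparison) ->
optional interventions (exchanger block, I_CaL kinetics).  Every stage
writes a CSV table with a stable name; a manifest records config, seed and
package version so any single model can be re-simulated in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balance import series_balances
from .classification import APD_ALTERNANS_THRESHOLD
from .interventions import (block_conversion_summary, ical_kinetics_study,
                            inaca_block_study, kinetics_fit)
from .invivo import ARIGeneratorParams, generate_ari_study
from .ord import SCALING_NAMES, ParameterScaling, build_model
from .population import CalibrationRanges, evaluate_population, lhs_sample
from .protocols import DEFAULT_CLS, PacingProtocol, pace
from .stats import correlation_report, mann_whitney

__all__ = ["StudyConfig", "StudyReport", "run_study", "write_tables"]


@dataclass
class StudyConfig:
    """Fully serializable study configuration (defaults = full-scale study)."""

    n_models: int = 10000
    seed: int = 1
    cl_list: tuple = DEFAULT_CLS
    n_prebeats: int = 500
    n_record: int = 4
    apd_alternans_threshold: float = APD_ALTERNANS_THRESHOLD
    ranges_file: str | None = None      # YAML envelopes; None -> synthetic
    invivo_params: dict = field(default_factory=dict)
    run_block_study: bool = True
    run_kinetics_study: bool = True
    block_fractions: tuple = (0.2, 0.4, 0.6)
    outdir: str = "study_output"
    workers: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cl_list"] = list(self.cl_list)
        d["block_fractions"] = list(self.block_fractions)
        return d

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["cl_list"] = tuple(payload.get("cl_list", DEFAULT_CLS))
        payload["block_fractions"] = tuple(
            payload.get("block_fractions", (0.2, 0.4, 0.6)))
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def protocol(self) -> PacingProtocol:
        return PacingProtocol(cl_list=tuple(float(c) for c in self.cl_list),
                              n_prebeats=self.n_prebeats,
                              n_record=self.n_record)


@dataclass
class StudyReport:
    config: StudyConfig
    ranges: CalibrationRanges
    population: pd.DataFrame
    balance: pd.DataFrame
    pcc: pd.DataFrame | None
    group_comparison: pd.DataFrame
    block_result: pd.DataFrame | None = None
    block_summary: pd.DataFrame | None = None
    kinetics_result: pd.DataFrame | None = None
    errors: list = field(default_factory=list)


def _make_ranges(config: StudyConfig) -> CalibrationRanges:
    if config.ranges_file:
        return CalibrationRanges.from_yaml(config.ranges_file)
    params = ARIGeneratorParams(**config.invivo_params) \
        if config.invivo_params else ARIGeneratorParams()
    study = generate_ari_study(cl_list=config.cl_list, params=params,
                               seed=config.seed)
    return study.ranges


def _alternans_rows(population: pd.DataFrame) -> pd.DataFrame:
    acc = population[population.verdict == "accepted"]
    return acc[acc.label.isin(["eye", "fork", "cat_only"])]


def _balance_tables(population, config) -> pd.DataFrame:
    """Per-beat SRCB/SCB for every alternans model at every captured CL."""
    proto = config.protocol()
    frames = []
    for _, row in _alternans_rows(population).iterrows():
        scaling = ParameterScaling.from_array(
            row[list(SCALING_NAMES)].to_numpy(dtype=float))
        spec = build_model(scaling)
        state = None
        for cl in proto.cl_list:
            series = pace(spec, cl, proto.n_prebeats, max(proto.n_record, 4),
                          initial_state=state)
            state = series.final_state
            tab = series_balances(series, model_id=int(row.model_id))
            tab["label"] = row.label
            tab["dapd_ms"] = row.get(f"dapd_{int(cl)}", np.nan)
            frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=["model_id", "cl_ms", "beat_index",
                                     "apd_ms", "parity", "srcb_umol_per_l",
                                     "scb_umol_per_l", "label", "dapd_ms"])
    return pd.concat(frames, ignore_index=True)


_PCC_BIOMARKERS = ("apd", "APA", "Vmax", "RMP", "UPD", "Tri",
                   "CaTmax", "CaTmin", "CaTD")


def _statistics(population: pd.DataFrame, config: StudyConfig):
    acc = population[population.verdict == "accepted"]
    pcc = None
    cl_ref = int(min(config.cl_list))
    n_params = len(SCALING_NAMES)
    if len(acc) >= n_params + 2:
        bio_cols = {b: f"{b}_{cl_ref}" for b in _PCC_BIOMARKERS}
        biom = acc[[c for c in bio_cols.values() if c in acc.columns]]
        biom = biom.rename(columns={v: k for k, v in bio_cols.items()})
        try:
            pcc = correlation_report(acc[list(SCALING_NAMES)], biom).pcc
        except (ValueError, np.linalg.LinAlgError):
            pcc = None
    rows = []
    normal = acc[acc.label == "normal"]
    alt = _alternans_rows(population)
    if len(normal) > 0 and len(alt) > 0:
        for name in SCALING_NAMES:
            mw = mann_whitney(alt[name].to_numpy(), normal[name].to_numpy())
            rows.append({
                "parameter": name,
                "alternans_median": float(alt[name].median()),
                "normal_median": float(normal[name].median()),
                "U": mw["U"], "p": mw["p"], "stars": mw["stars"],
            })
    return pcc, pd.DataFrame(rows)


def run_study(config: StudyConfig, progress: bool = False) -> StudyReport:
    """Execute the full pipeline; partial results survive stage failures."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    probe.write_text("ok")  # fail before simulating if unwritable
    probe.unlink()

    errors = []
    ranges = _make_ranges(config)
    samples = lhs_sample(config.n_models, seed=config.seed)
    proto = config.protocol()
    population = evaluate_population(samples, proto, ranges=ranges,
                                     progress=progress)
    # checkpoint the expensive stage immediately
    population.to_csv(outdir / "population.csv", index=False)

    try:
        balance = _balance_tables(population, config)
    except Exception as err:  # pragma: no cover - defensive
        errors.append(f"balance: {err}")
        balance = pd.DataFrame()
    pcc, groups = _statistics(population, config)

    block_result = block_summary = kinetics_result = None
    alt = _alternans_rows(population)
    if config.run_block_study and len(alt) > 0:
        try:
            models = [(int(r.model_id),
                       ParameterScaling.from_array(
                           r[list(SCALING_NAMES)].to_numpy(dtype=float)),
                       r.label) for _, r in alt.iterrows()]
            block_result = inaca_block_study(models, proto,
                                             config.block_fractions)
            block_summary = block_conversion_summary(block_result)
        except Exception as err:
            errors.append(f"block_study: {err}")
    apd_alt = alt[alt.label.isin(["eye", "fork"])]
    if config.run_kinetics_study and len(apd_alt) > 0:
        try:
            frames = []
            for label in ("eye", "fork"):
                grp = apd_alt[apd_alt.label == label]
                if grp.empty:
                    continue
                dapd_cols = [f"dapd_{int(c)}" for c in config.cl_list]
                peak = grp[dapd_cols].max(axis=1)
                biggest = grp.loc[peak.idxmax()]
                cl_star = float(config.cl_list[int(np.nanargmax(
                    biggest[dapd_cols].to_numpy(dtype=float)))])
                scaling = ParameterScaling.from_array(
                    biggest[list(SCALING_NAMES)].to_numpy(dtype=float))
                study = ical_kinetics_study(scaling, cl_star, proto,
                                            model_id=int(biggest.model_id))
                study["pre_label"] = label
                study["cl_ms"] = cl_star
                frames.append(study)
            if frames:
                kinetics_result = pd.concat(frames, ignore_index=True)
        except Exception as err:
            errors.append(f"kinetics_study: {err}")

    report = StudyReport(config=config, ranges=ranges, population=population,
                         balance=balance, pcc=pcc, group_comparison=groups,
                         block_result=block_result, block_summary=block_summary,
                         kinetics_result=kinetics_result, errors=errors)
    write_tables(report, outdir)
    return report


def write_tables(report: StudyReport, outdir) -> list:
    """Write all result tables (CSV + HDF5 mirror of the population table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df, name):
        if df is None:
            return
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    _w(report.population, "population.csv")
    report.ranges.to_yaml(outdir / "calibration_ranges.yaml")
    written.append(outdir / "calibration_ranges.yaml")
    acc = report.population[report.population.get("verdict") == "accepted"] \
        if "verdict" in report.population else report.population
    cls_cols = [c for c in ("model_id", "label", "onset_cl") if c in acc.columns]
    dapd_cols = [c for c in acc.columns if str(c).startswith("dapd_")]
    _w(acc[cls_cols + dapd_cols] if cls_cols else pd.DataFrame(),
       "classification.csv")
    _w(report.balance, "balance.csv")
    if report.pcc is not None:
        path = outdir / "partial_correlation.csv"
        report.pcc.to_csv(path)
        written.append(path)
    _w(report.group_comparison, "group_comparison.csv")
    _w(report.block_result, "interventions_block.csv")
    _w(report.block_summary, "interventions_block_summary.csv")
    _w(report.kinetics_result, "interventions_kinetics.csv")

    try:
        import h5py
        with h5py.File(outdir / "population.h5", "w") as fh:
            grp = fh.create_group("population")
            for col in report.population.columns:
                data = report.population[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                grp.create_dataset(str(col), data=data)
        written.append(outdir / "population.h5")
    except Exception as err:  # pragma: no cover
        report.errors.append(f"hdf5: {err}")

    manifest = {
        "package_version": __version__,
        "config": report.config.to_dict(),
        "config_hash": report.config.config_hash(),
        "n_models": int(len(report.population)),
        "n_accepted": int((report.population.get("verdict") == "accepted").sum())
        if "verdict" in report.population else None,
        "errors": report.errors,
        "tables": [p.name for p in written],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return written
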