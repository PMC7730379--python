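"""End-to-end orchestration of a simulation run.

For every individual: sample person-level parameters, generate exposure
events over accumulation + window, assign a void schedule, solve the
kinetics void-by-void, take the window AUC, collect samples under the timing
scheme, and pool.  The run then assembles the reliability report and
(optionally) writes the CSV outputs plus a manifest that fully determines a
reproducible re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    SamplingDayMode,
    ScenarioConfig,
    Standardization,
    config_checksum_payload,
    substream,
)
from .metrics import ReliabilityReport, build_report
from .pk import PKParams, VoidConcentrations, void_concentrations, window_auc
from .population import ExposureEvents, Individual, generate_exposure_events, sample_individual
from .sampling import CollectedSamples, pooled_means, sampling_days, select_samples
from .schedules import ScheduleTemplate, VoidSchedule, assign_schedule, build_template_bank

__all__ = ["SimulationResult", "RunManifest", "run", "export_temporal", "write_outputs"]

logger = logging.getLogger("spotsim")


def _package_version() -> str:
    try:
        return _pkg_version("spotsim")
    except PackageNotFoundError:  # pragma: no cover - source tree without install
        return "0.0.0+src"


@dataclass
class SimulationResult:
    """Everything a run produced, per individual and aggregated."""

    config: ScenarioConfig
    individuals: list[Individual]
    events: list[ExposureEvents] = field(repr=False)
    schedules: list[VoidSchedule] = field(repr=False)
    concentrations: list[VoidConcentrations] = field(repr=False)
    aucs: np.ndarray = field(repr=False)
    sample_matrix: np.ndarray = field(repr=False)  # (n_individuals, max_samples)
    pools: dict[int, np.ndarray] = field(repr=False)
    report: ReliabilityReport | None = None


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, version, timing, outputs."""

    config: dict
    seed: int
    software_version: str
    started_utc: float
    finished_utc: float
    outputs: dict[str, str]  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "software_version": self.software_version,
                "started_utc": self.started_utc,
                "finished_utc": self.finished_utc,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _simulate_individual(
    i: int,
    config: ScenarioConfig,
    bank: list[ScheduleTemplate],
    days: np.ndarray,
) -> tuple[Individual, ExposureEvents, VoidSchedule, VoidConcentrations, float, CollectedSamples]:
    seed = config.seed
    individual = sample_individual(i, config, substream(seed, "params", i))
    events = generate_exposure_events(individual, config, substream(seed, "exposure", i))
    schedule = assign_schedule(bank, config.total_days, substream(seed, "schedule", i))
    individual = Individual(
        index=i, gm_dose=individual.gm_dose, half_life=individual.half_life,
        schedule_id=schedule.template_id,
    )
    params = PKParams.from_half_lives(
        config.absorption_half_life, individual.half_life, config.fraction_excreted
    )
    conc = void_concentrations(events.times, events.doses, params, schedule, config.sg_reference)
    auc = window_auc(events.times, events.doses, params, config.window_start_h, config.window_end_h)
    samples = select_samples(conc, schedule, config, days, substream(seed, "sampling", i))
    return individual, events, schedule, conc, auc, samples


def run(config: ScenarioConfig, bank: list[ScheduleTemplate] | None = None) -> tuple[SimulationResult, ReliabilityReport]:
    """Run the full Monte Carlo simulation described by ``config``.

    ``bank`` overrides the synthetic schedule-template bank (e.g. templates
    loaded from a user CSV); by default a fresh synthetic bank is generated
    from the run's own seed substream.
    """
    t0 = time.perf_counter()
    if bank is None:
        bank = build_template_bank(
            config.n_schedule_templates,
            config.schedule_days_per_template,
            substream(config.seed, "bank"),
        )
    day_rng = substream(config.seed, "days")
    days = sampling_days(config.window_days, config.max_samples, config.sampling_day_mode, day_rng)

    individuals, events, schedules, concs, samples_rows = [], [], [], [], []
    aucs = np.empty(config.n_individuals)
    for i in range(config.n_individuals):
        try:
            ind, ev, sch, conc, auc, samples = _simulate_individual(i, config, bank, days)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for individual {i}: {exc}") from exc
        individuals.append(ind)
        events.append(ev)
        schedules.append(sch)
        concs.append(conc)
        aucs[i] = auc
        samples_rows.append(samples.concentrations)
    sample_matrix = np.vstack(samples_rows)
    pools = pooled_means(sample_matrix)
    logger.info(
        "simulated %d individuals (%d days each) in %.2f s",
        config.n_individuals, config.total_days, time.perf_counter() - t0,
    )

    report = build_report(aucs, pools, sample_matrix)
    result = SimulationResult(
        config=config,
        individuals=individuals,
        events=events,
        schedules=schedules,
        concentrations=concs,
        aucs=aucs,
        sample_matrix=sample_matrix,
        pools=pools,
        report=report,
    )
    if report.icc_raw is not None and report.icc_raw < 0:
        logger.warning("negative ANOVA ICC (%.4g) was clipped to 0", report.icc_raw)
    return result, report


# ----------------------------------------------------------------------------
# Output files
# ----------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_temporal(result: SimulationResult, individual_index: int, out_dir: str | Path) -> list[Path]:
    """Write one individual's intake and void-concentration time series.

    Produces ``temporal_intake_<i>.csv`` (time_h, dose) and
    ``temporal_voids_<i>.csv`` (void_time_h, concentration_raw,
    concentration_std) mirroring the temporal-variation output.
    """
    if not 0 <= individual_index < len(result.individuals):
        raise IndexError(f"individual index {individual_index} out of range 0..{len(result.individuals) - 1}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ev = result.events[individual_index]
    intake = pd.DataFrame({"time_h": ev.times, "dose": ev.doses})
    conc = result.concentrations[individual_index]
    sch = result.schedules[individual_index]
    std = {
        Standardization.none: conc.raw,
        Standardization.creatinine: conc.creatinine_std,
        Standardization.specific_gravity: conc.sg_std,
    }[result.config.standardization]
    voids = pd.DataFrame(
        {"void_time_h": sch.times, "concentration_raw": conc.raw, "concentration_std": std}
    )
    paths = [
        out_dir / f"temporal_intake_{individual_index}.csv",
        out_dir / f"temporal_voids_{individual_index}.csv",
    ]
    intake.to_csv(paths[0], index=False)
    voids.to_csv(paths[1], index=False)
    return paths


def write_outputs(
    result: SimulationResult,
    out_dir: str | Path,
    started_utc: float | None = None,
) -> RunManifest:
    """Write the report tables and the run manifest to ``out_dir``.

    Files: r2_by_n.csv, accuracy_by_n.csv, icc.txt, scatter_max_n.csv,
    manifest.json.  Numeric formatting is fixed so identical runs produce
    bitwise-identical files.
    """
    report = result.report
    if report is None:
        raise ValueError("simulation result carries no report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time() if started_utc is None else started_utc

    files: dict[str, str] = {}
    r2_path = out_dir / "r2_by_n.csv"
    report.r2_table().to_csv(r2_path, index=False, float_format="%.10g")
    acc_path = out_dir / "accuracy_by_n.csv"
    report.accuracy_table().to_csv(acc_path, index=False, float_format="%.10g")
    icc_path = out_dir / "icc.txt"
    if report.icc is None:
        icc_path.write_text("ICC: not defined (max_samples < 2)\n")
    else:
        icc_path.write_text(f"ICC: {report.icc:.10g}\nICC_raw: {report.icc_raw:.10g}\n")
    scatter_path = out_dir / "scatter_max_n.csv"
    report.scatter_max_n.to_csv(scatter_path, index=False, float_format="%.10g")
    for p in (r2_path, acc_path, icc_path, scatter_path):
        files[p.name] = _sha256(p)

    manifest = RunManifest(
        config=json.loads(config_checksum_payload(result.config)),
        seed=result.config.seed,
        software_version=_package_version(),
        started_utc=t_start,
        finished_utc=time.time(),
        outputs=files,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def plot_report(report: ReliabilityReport, out_dir: str | Path) -> list[Path]:
    """Optional PNG plots of the three output surfaces (regression curve,
    scatter at max n, classification accuracy)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    ns = sorted(report.r2_by_n)
    ax.plot(ns, [report.r2_by_n[n] for n in ns], "o-")
    ax.set_xlabel("number of pooled urine samples")
    ax.set_ylabel(r"$R^2$, log AUC vs log mean concentration")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    paths.append(out_dir / "r2_curve.png")
    fig.savefig(paths[-1], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(report.scatter_max_n["pooled_concentration"], report.scatter_max_n["auc_window"], ".", alpha=0.3)
    ax.set_xlabel("pooled mean concentration (max samples)")
    ax.set_ylabel("window AUC (internal exposure)")
    fig.tight_layout()
    paths.append(out_dir / "scatter_max_n.png")
    fig.savefig(paths[-1], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ns, [report.tertile_accuracy_by_n[n] for n in ns], "o-", label="tertiles")
    ax.plot(ns, [report.quartile_accuracy_by_n[n] for n in ns], "s-", label="quartiles")
    ax.set_xlabel("number of pooled urine samples")
    ax.set_ylabel("% correctly classified")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    paths.append(out_dir / "accuracy_curve.png")
    fig.savefig(paths[-1], dpi=120)
    plt.close(fig)
    return paths
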