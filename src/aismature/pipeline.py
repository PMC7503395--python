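"""End-to-end orchestration: cohort -> per-cell features -> derived -> stats.

``run_pipeline`` consumes either an in-memory :class:`~aismature.synth.Cohort`
or a cohort directory (``group/animal/cell/{sealtest.csv, steps_*/*.csv,
ais_profile.csv}``), analyzes every cell, measures every AIS profile,
derives the group-level biophysics (AIS capacitance, estimated AIS inward
current, the rheobase-Rin hyperbola) and runs the group statistics. A cell
that fails any stage is logged and skipped; the run continues.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biophysics, firing, group_stats, morphometry, passive, waveform
from .exceptions import AismatureError
from .synth import CellData, Cohort, load_profile
from .trace_io import read_trace_table

__all__ = ["RunConfig", "PipelineResult", "analyze_cell", "run_pipeline"]

#: variables compared across groups with cells as biological replicates
EPHYS_VARIABLES = [
    "cm_pF", "rin_Mohm", "rheobase_pA", "threshold_mV", "gain_Hz_per_pA",
    "max_freq_Hz", "max_dvdt_Vps", "half_width_ms", "est_i_in_ais_pA",
]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, hashable for the manifest."""

    seed: int = 0
    alpha: float = 0.05
    posthoc_always: bool = False
    specific_capacitance_uF_cm2: float = 1.0
    ais_threshold_fraction: float = 0.3
    phase_criterion_Vps: float = 20.0
    variables: list = field(default_factory=lambda: list(EPHYS_VARIABLES))

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    features: pd.DataFrame  # one row per analyzed cell
    ais: pd.DataFrame  # one row per measured AIS profile
    group_derived: pd.DataFrame  # per-group AIS geometry and capacitance
    hyperbola: biophysics.HyperbolaFit | None
    comparisons: dict  # variable -> GroupComparison
    failures: list  # (cell id, stage, message)
    log: list
    manifest: dict


def analyze_cell(cell: CellData, config: RunConfig | None = None) -> dict:
    """All per-cell feature extraction; returns one flat feature record."""
    config = config or RunConfig()
    props = passive.analyze_seal_test(cell.sealtest)
    erest = passive.measure_erest(cell.rheo_protocol.traces[0])
    rheo = firing.find_rheobase(cell.rheo_protocol)

    curve = firing.fi_curve(cell.fi_protocol)
    gain, i_at_gain = firing.io_gain(curve)
    fmax = float(np.max(curve.frequencies))

    # waveform metrics from the first AP of the rheobase step
    k = int(np.argmax(cell.rheo_protocol.injected_amplitudes >= rheo))
    tr = cell.rheo_protocol.traces[k]
    train = firing.detect_spikes(tr)
    pk = int(train.spike_peak_indices[0])
    nxt = int(train.spike_peak_indices[1]) if train.n_spikes > 1 else None
    pp = waveform.phase_plot(tr, pk)
    thr = waveform.ap_threshold(pp, config.phase_criterion_Vps)
    max_dvdt, min_dvdt = waveform.slope_extrema(pp)
    hw = waveform.ap_half_width(tr, thr, pk)
    issd = waveform.is_sd_components(pp, criterion_vps=config.phase_criterion_Vps)
    ahp = waveform.ahp_adp_profile(tr, pk, thr, next_spike_peak_index=nxt)

    ais_m = morphometry.measure_ais(
        cell.ais_profile, config.ais_threshold_fraction)
    diam = morphometry.fwhm(cell.ais_cross_profile.positions,
                            cell.ais_cross_profile.intensities)

    return {
        "group": cell.group,
        "animal_id": cell.animal_id,
        "cell_id": cell.cell_id,
        "cm_pF": props.Cm,
        "rin_Mohm": props.Rin,
        "rs_Mohm": props.Rs,
        "tau_ms": props.tau,
        "erest_mV": erest,
        "rheobase_pA": rheo,
        "gain_Hz_per_pA": gain,
        "current_at_max_gain_pA": i_at_gain,
        "max_freq_Hz": fmax,
        "threshold_mV": thr,
        "max_dvdt_Vps": max_dvdt,
        "min_dvdt_Vps": min_dvdt,
        "half_width_ms": hw,
        "is_peak_Vps": issd.is_peak,
        "sd_peak_Vps": issd.sd_peak if issd.biphasic else np.nan,
        "biphasic": issd.biphasic,
        "ahp_class": ahp.shape_class,
        "ahp_slow_mono_mV": ahp.ahp_slow_mono,
        "depol_at_rheobase_mV": biophysics.depolarization_at_rheobase(erest, thr),
        "ais_length_um": ais_m.length_um,
        "ais_start_um": ais_m.start_um,
        "ais_diameter_um": diam,
    }


def _cells_from_dir(root: Path):
    for seal in sorted(root.glob("*/*/*/sealtest.csv")):
        cdir = seal.parent
        yield f"{cdir.parent.parent.name}/{cdir.parent.name}/{cdir.name}", cdir


def _load_cell(cdir: Path) -> CellData:
    from .trace_io import StepProtocolSet

    def load_steps(sub):
        traces = [read_trace_table(p) for p in sorted((cdir / sub).glob("*.csv"))]
        traces.sort(key=lambda t: t.step_amplitude)
        amps = np.array([t.step_amplitude for t in traces])
        dur = traces[0].step_window[1] - traces[0].step_window[0]
        return StepProtocolSet(traces=traces, injected_amplitudes=amps, step_duration=dur)

    return CellData(
        group=cdir.parent.parent.name,
        animal_id=cdir.parent.name,
        cell_id=cdir.name,
        truth={},
        sealtest=read_trace_table(cdir / "sealtest.csv"),
        rheo_protocol=load_steps("steps_rheo"),
        fi_protocol=load_steps("steps_fi"),
        ais_profile=load_profile(cdir / "ais_profile.csv"),
        ais_cross_profile=load_profile(cdir / "ais_cross_profile.csv"),
    )


def _iter_source(source):
    """Yield (cell_key, loader) pairs for a Cohort or a cohort directory."""
    if isinstance(source, Cohort):
        for cell in source.cells:
            key = f"{cell.group}/{cell.animal_id}/{cell.cell_id}"
            yield key, (lambda c=cell: c)
    else:
        root = Path(source)
        for key, cdir in _cells_from_dir(root):
            yield key, (lambda d=cdir: _load_cell(d))


def _ais_arm(source, config: RunConfig):
    rows = []
    if isinstance(source, Cohort):
        items = ((g, a, i, p) for g, a, i, p in source.ais_profiles)
    else:
        root = Path(source)
        items = (
            (p.parent.parent.parent.name, p.parent.parent.name, p.stem, load_profile(p))
            for p in sorted(root.glob("*/*/ais/*.csv"))
        )
    for group, animal, ais_id, prof in items:
        try:
            m = morphometry.measure_ais(prof, config.ais_threshold_fraction)
        except AismatureError:
            continue
        rows.append({"group": group, "animal_id": animal, "ais_id": ais_id,
                     "length_um": m.length_um, "start_um": m.start_um})
    return pd.DataFrame(rows)


def run_pipeline(
    source,
    out_dir=None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full analysis over a cohort (in memory or on disk).

    Per-cell failures are isolated: the offending cell is logged under
    ``result.failures`` and excluded from the tables, and the run continues.
    """
    config = config or RunConfig()
    log: list[str] = []
    failures: list[tuple[str, str]] = []
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key, loader in _iter_source(source):
            try:
                rec = analyze_cell(loader(), config)
                records.append(rec)
                log.append(f"ok {key}")
            except (AismatureError, OSError, KeyError) as err:
                failures.append((key, f"{type(err).__name__}: {err}"))
                log.append(f"FAIL {key}: {type(err).__name__}: {err}")
    features = pd.DataFrame(records)

    ais = _ais_arm(source, config)

    # group-level derived biophysics
    group_rows = []
    est_col = np.full(len(features), np.nan)
    if not ais.empty and not features.empty:
        for group, sub in ais.groupby("group", sort=False):
            mean_len = float(sub["length_um"].mean())
            sel = features["group"] == group
            mean_diam = float(features.loc[sel, "ais_diameter_um"].mean()) if sel.any() else np.nan
            if np.isfinite(mean_diam):
                cap = biophysics.ais_capacitance(
                    mean_len, mean_diam, config.specific_capacitance_uF_cm2)
                group_rows.append({
                    "group": group, "mean_ais_length_um": mean_len,
                    "mean_ais_diameter_um": mean_diam, "c_ais_pF": cap.c_ais,
                })
                est = cap.c_ais * features.loc[sel, "is_peak_Vps"]
                est_col[np.flatnonzero(sel.to_numpy())] = est
    if not features.empty:
        features["est_i_in_ais_pA"] = est_col
    group_derived = pd.DataFrame(group_rows)

    hyper = None
    if len(features) >= 2:
        hyper = biophysics.fit_rheobase_hyperbola(
            features[["rin_Mohm", "rheobase_pA"]].to_numpy())

    comparisons = {}
    if not features.empty and features["group"].nunique() >= 2:
        for var in config.variables:
            if var not in features.columns:
                continue
            sub = features.dropna(subset=[var])
            try:
                gm = group_stats.GroupedMeasurements.from_frame(
                    sub, "group", var, replicate_mode="cell_as_unit")
                comparisons[var] = group_stats.compare_groups(
                    gm, config.alpha, posthoc_always=config.posthoc_always)
            except AismatureError as err:
                log.append(f"stats skipped for {var}: {err}")
    if not ais.empty and ais["group"].nunique() >= 2:
        try:
            gm = group_stats.GroupedMeasurements.from_frame(
                ais, "group", "length_um", replicate_mode="animal_mean_as_unit")
            comparisons["ais_length_um"] = group_stats.compare_groups(
                gm, config.alpha, posthoc_always=config.posthoc_always)
        except AismatureError as err:
            log.append(f"stats skipped for ais_length_um: {err}")

    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": {k: v for k, v in config.__dict__.items()},
        "n_cells_analyzed": int(len(features)),
        "n_cells_failed": len(failures),
        "n_ais_measured": int(len(ais)),
        "hyperbola_V_mV": None if hyper is None else hyper.V,
    }

    result = PipelineResult(
        features=features, ais=ais, group_derived=group_derived,
        hyperbola=hyper, comparisons=comparisons, failures=failures,
        log=log, manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), config)
    return result


def _write_outputs(result: PipelineResult, out: Path, config: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    result.ais.to_csv(out / "ais.csv", index=False)
    result.group_derived.to_csv(out / "group_derived.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
    (out / "run.log").write_text("\n".join(result.log) + "\n")
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for var, cmp_ in result.comparisons.items():
        group_stats.render_summary(cmp_).to_csv(stats_dir / f"{var}.csv", index=False)
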