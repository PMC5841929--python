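"""End-to-end session analysis: behaviour -> QC -> spatial -> bursts ->
phase locking -> ripples, plus the two-group report.

Every stage logs the number of items passing its filters so the n behind
each downstream statistic is auditable. All numeric tables are written
as tab-separated text; a fixed seed makes the whole pipeline (simulation
included) deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, bursts, group_stats, io, lfp as lfp_mod, popvec, ripples, spatial, synth, unit_quality

log = logging.getLogger("ca1ephys")


@dataclass
class PipelineConfig:
    """Serialisable bundle of every stage parameter."""

    seed: int = 0
    synth: dict = field(default_factory=dict)       # SynthConfig overrides
    bin_cm: float = 1.0
    smooth_sd_bins: float = 1.0
    vmin_run_cm_s: float = 2.0
    vmin_phase_cm_s: float = 6.0
    jump_cm_s: float = 150.0
    pos_smooth_sd_s: float = 0.05
    vel_smooth_sd_samples: float = 2.5
    ripple: dict = field(default_factory=dict)      # RippleDetectionParams overrides

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def synth_config(self) -> synth.SynthConfig:
        return synth.SynthConfig(seed=self.seed, **self.synth)

    def ripple_params(self) -> ripples.RippleDetectionParams:
        return ripples.RippleDetectionParams(**self.ripple)


def analyze_session(bundle: dict, cfg: PipelineConfig = None) -> dict:
    """Run every analysis stage on one session bundle.

    Returns a dict of result tables/objects; see ``run_analysis`` for the
    on-disk layout.
    """
    cfg = cfg or PipelineConfig()
    pos_raw = bundle["position"]
    trains = bundle["spikes"]
    lfp_sig = bundle["lfp"]
    epochs = bundle["epochs"]

    # --- behaviour ---------------------------------------------------
    cleaned, n_repaired = behavior.clean_positions(pos_raw, cfg.jump_cm_s)
    pos = behavior.smooth_positions(cleaned, cfg.pos_smooth_sd_s)
    vel = behavior.compute_velocity(pos, cfg.vel_smooth_sd_samples)
    lin = behavior.project_to_track(pos)
    track_len = float(lin.max())
    laps = behavior.detect_laps(pos, track_len)
    log.info("behaviour: %d samples (%d repaired), %d laps",
             len(pos), n_repaired, len(laps))

    run_iv = epochs.run[0] if epochs.run else (0.0, pos.t[-1])
    rest_iv = epochs.rest[0] if epochs.rest else None

    # --- unit QC + classification ------------------------------------
    all_features = {tr.unit_id: tr.features for tr in trains}
    qc_rows = []
    for tr in trains:
        run_tr = tr.in_interval(*run_iv)
        if tr.n_spikes < 2:
            log.warning("unit %s: <2 spikes, excluded", tr.unit_id)
            continue
        noise = np.vstack([f for uid, f in all_features.items()
                           if uid != tr.unit_id])
        iso = unit_quality.isolation_distance(tr.features, noise)
        viol = unit_quality.isi_violation_fraction(tr.t)
        if run_tr.n_spikes >= 2:
            csi, _, _ = bursts.csi_for_train(run_tr)
        else:
            csi = float("nan")
        qc = unit_quality.UnitQC(tr.unit_id, viol, tr.n_spikes, iso, csi,
                                 tr.width_us)
        qc_rows.append(unit_quality.classify_unit(qc))
    qc_df = pd.DataFrame([vars(q) for q in qc_rows])
    pyramidal_ids = set(qc_df.loc[(qc_df.status == "included")
                                  & (qc_df.cell_class == "pyramidal"),
                                  "unit_id"]) if len(qc_df) else set()
    log.info("QC: %d/%d units included, %d pyramidal",
             int((qc_df.status == "included").sum()) if len(qc_df) else 0,
             len(trains), len(pyramidal_ids))

    # --- spatial + bursts + phase locking per pyramidal unit ---------
    theta = lfp_mod.theta_phase(lfp_sig.segment(*run_iv))
    unit_rows, curves, place_ids = [], [], []
    for tr in trains:
        if tr.unit_id not in pyramidal_ids:
            continue
        run_tr = tr.in_interval(*run_iv)
        sm = spatial.unit_spatial_metrics(tr.unit_id, run_tr, lin, pos, vel,
                                          laps, track_len, cfg.bin_cm)
        run_bursts = bursts.detect_bursts(run_tr.t)
        bs_run = bursts.burst_statistics(run_bursts, run_tr.t,
                                         run_iv[1] - run_iv[0])
        row = {
            "unit_id": tr.unit_id, "peak_rate_hz": sm.peak_rate,
            "mean_rate_hz": sm.mean_rate, "infield_rate_hz": sm.infield_rate,
            "outfield_rate_hz": sm.outfield_rate,
            "field_size_bins": sm.field_size_bins,
            "si_bits_per_s": sm.si_bits_per_s, "sparsity": sm.sparsity,
            "snr": sm.snr, "di": sm.di, "is_place_cell": sm.is_place_cell,
            "bursts_per_min_run": bs_run.bursts_per_min,
            "pct_spikes_in_burst_run": bs_run.pct_spikes_in_burst,
            "spikes_per_burst_run": bs_run.spikes_per_burst,
            "mean_interburst_s_run": bs_run.mean_interburst_s,
            "mean_burst_duration_ms_run": bs_run.mean_duration_ms,
        }
        if run_tr.n_spikes >= 2:
            row["isi_mode_ms"] = bursts.isi_histogram_mode(tr.t)[0]
        if rest_iv is not None:
            rest_tr = tr.in_interval(*rest_iv)
            if rest_tr.n_spikes >= 2:
                bs_rest = bursts.burst_statistics(
                    bursts.detect_bursts(rest_tr.t), rest_tr.t,
                    rest_iv[1] - rest_iv[0])
                row["bursts_per_min_rest"] = bs_rest.bursts_per_min
                row["pct_spikes_in_burst_rest"] = bs_rest.pct_spikes_in_burst
                csi_rest, _, _ = bursts.csi_for_train(rest_tr)
                row["csi_rest"] = csi_rest
        try:
            ph = lfp_mod.spike_phase_stats(run_tr, theta, vel,
                                           cfg.vmin_phase_cm_s)
            row.update(preferred_phase_deg=ph.preferred_phase_deg,
                       resultant_r=ph.resultant_r, rayleigh_p=ph.rayleigh_p,
                       kl_div=ph.kl_div, mod_index=ph.mod_index,
                       theta_modulated=ph.significant and not ph.low_n)
        except Exception:
            row["theta_modulated"] = False
        unit_rows.append(row)
        if sm.is_place_cell:
            place_ids.append(tr.unit_id)
            left, right = spatial.compute_rate_curves(
                run_tr, lin, pos, vel, laps, track_len, cfg.bin_cm)
            curves.append((left.rate, right.rate))
    unit_df = pd.DataFrame(unit_rows)
    if len(qc_df):
        unit_df = qc_df.merge(unit_df, on="unit_id", how="left") \
            if len(unit_df) else qc_df
    log.info("spatial: %d place cells of %d pyramidal units",
             len(place_ids), len(pyramidal_ids))

    # --- population vectors ------------------------------------------
    pv_result = None
    if len(curves) >= 2:
        pv = popvec.build_population_vectors(curves, cfg.bin_cm)
        pm = popvec.pv_correlation_matrix(pv)
        pv_result = {
            "matrix": pm,
            "profile_same": popvec.distance_profile(pm, "same", cfg.bin_cm),
            "profile_opposite": popvec.distance_profile(pm, "opposite",
                                                        cfg.bin_cm),
        }

    # --- ripples -------------------------------------------------------
    ripple_result = None
    if rest_iv is None:
        log.info("ripples: no rest epoch, stage skipped")
    else:
        params = cfg.ripple_params()
        rest_lfp = lfp_sig.segment(*rest_iv)
        events = ripples.detect_ripples_full(rest_lfp, trains, params)
        metrics = ripples.ripple_metrics(events, rest_iv[1] - rest_iv[0])
        pyr_trains = [tr for tr in trains if tr.unit_id in pyramidal_ids]
        unit_stats = [ripples.ripple_unit_stats(events, tr)
                      for tr in pyr_trains]
        log.info("ripples: %d gated events, rate %.2f/min",
                 metrics.n_events, metrics.rate_per_min)
        ripple_result = {"events": events, "metrics": metrics,
                         "unit_stats": unit_stats}

    return {"qc": qc_df, "units": unit_df, "laps": laps,
            "n_repaired": n_repaired, "pv": pv_result,
            "ripples": ripple_result, "place_ids": place_ids}


def _write_tables(out: Path, result: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result["units"].to_csv(out / "units.tsv", sep="\t", index=False,
                           float_format="%.6f")
    laps_df = pd.DataFrame([vars(l) for l in result["laps"]])
    laps_df.to_csv(out / "laps.tsv", sep="\t", index=False,
                   float_format="%.6f")
    if result["ripples"] is not None:
        ev = result["ripples"]["events"]
        pd.DataFrame([{
            "t_start": e.t_start, "t_end": e.t_end, "t_peak": e.t_peak,
            "duration_ms": e.duration_ms,
            "core_duration_ms": e.core_duration_ms,
            "amplitude_sd": e.amplitude_sd,
            "peak_freq_hz": e.peak_freq_hz,
        } for e in ev]).to_csv(out / "ripple_events.tsv", sep="\t",
                               index=False, float_format="%.6f")
        pd.DataFrame([vars(s) for s in result["ripples"]["unit_stats"]]) \
            .to_csv(out / "ripple_units.tsv", sep="\t", index=False,
                    float_format="%.6f")
        pd.DataFrame([vars(result["ripples"]["metrics"])]) \
            .to_csv(out / "ripple_metrics.tsv", sep="\t", index=False,
                    float_format="%.6f")


def run_simulation(cfg: PipelineConfig, out_dir) -> synth.SynthSession:
    session = synth.generate_session(cfg.synth_config())
    io.write_session(out_dir, session)
    return session


def run_analysis(session_dir, out_dir, cfg: PipelineConfig = None) -> dict:
    cfg = cfg or PipelineConfig()
    bundle = io.read_session(session_dir)
    result = analyze_session(bundle, cfg)
    _write_tables(Path(out_dir), result)
    return result


#: unit-level metrics compared across groups (Mann-Whitney) and the
#: animal-level ripple metrics compared by one-way ANOVA
UNIT_METRICS = ["peak_rate_hz", "mean_rate_hz", "infield_rate_hz",
                "outfield_rate_hz", "si_bits_per_s", "sparsity", "di", "csi",
                "bursts_per_min_run", "pct_spikes_in_burst_run",
                "spikes_per_burst_run", "isi_mode_ms",
                "bursts_per_min_rest", "pct_spikes_in_burst_rest",
                "csi_rest", "resultant_r", "mod_index"]
ANIMAL_METRICS = ["rate_per_min", "mean_iri_s", "mean_amplitude_sd",
                  "mean_duration_ms", "mean_peak_freq_hz"]


#: generator overrides for the synthetic "burst-deficit" genotype:
#: reduced complex-spike probability and weaker, shorter ripples
MUTANT_OVERRIDES = {"burst_prob": 0.10, "ripple_amp_sd": 4.0,
                    "ripple_duration_ms": 55.0}


def synthetic_genotype_contrast(seed: int = 0, n_animals: int = 5,
                                n_units: int = 10, n_laps: int = 4,
                                rest_duration_s: float = 300.0):
    """Two-group synthetic study: control vs burst/ripple-deficit group.

    Each animal is one simulated session; the deficit group has reduced
    burst probability and reduced ripple amplitude/duration. The rest
    epoch is 300 s (~50 ripple events per animal) so the per-animal
    ripple summaries have sampling error well below the injected group
    differences, as in the long rest recordings this emulates. Returns
    ``(results_control, results_deficit, report)`` where the report is
    the ``group_report`` comparison table.
    """
    base = dict(n_units=n_units, n_laps=n_laps,
                rest_duration_s=rest_duration_s)

    def run_group(overrides, seed_offset):
        results = []
        for k in range(n_animals):
            cfg = synth.SynthConfig(seed=seed + seed_offset + k,
                                    **base, **overrides)
            s = synth.generate_session(cfg)
            bundle = {"position": s.position, "spikes": s.spikes,
                      "lfp": s.lfp, "epochs": s.epochs, "truth": s.truth}
            results.append(analyze_session(bundle))
        return results

    results_a = run_group({}, 0)
    results_b = run_group(MUTANT_OVERRIDES, 10_000)
    return results_a, results_b, group_report(results_a, results_b)


def group_report(results_a: list, results_b: list) -> pd.DataFrame:
    """Two-group comparison table from per-session analysis results.

    Unit-level metrics pool units across a group's sessions and use the
    Mann-Whitney U test; ripple summaries are per-animal means compared
    with one-way ANOVA; unit ripple participation uses rank-sum.
    """
    def collect(results):
        m = {}
        units = pd.concat([r["units"] for r in results], ignore_index=True)
        units = units[units.get("status", "included") == "included"]
        for metric in UNIT_METRICS:
            if metric in units:
                m[metric] = units[metric].to_numpy(float)
        for metric in ANIMAL_METRICS:
            vals = [getattr(r["ripples"]["metrics"], metric)
                    for r in results if r["ripples"] is not None]
            if vals:
                m[metric] = np.array(vals, float)
        part, spr = [], []
        for r in results:
            if r["ripples"] is not None:
                part += [s.participation for s in r["ripples"]["unit_stats"]]
                spr += [s.spikes_per_ripple for s in r["ripples"]["unit_stats"]]
        if part:
            m["participation"] = np.array(part)
            m["spikes_per_ripple"] = np.array(spr)
        return m

    ma, mb = collect(results_a), collect(results_b)
    tests = {metric: "anova1" for metric in ANIMAL_METRICS}
    return group_stats.build_report(ma, mb, tests)
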