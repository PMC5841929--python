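"""Session file formats: columnar text + raw-binary LFP with JSON sidecar.

Layout of a session directory::

    position.tsv          t, x, y (s / cm)
    spikes/u000.tsv       t, amp0..amp3, f0..f7 per spike
    spikes/units.json     unit_id -> {width_us}
    lfp.bin               little-endian int16 raw samples
    lfp.json              {fs_hz, scale_uV, channel_id, t0}
    epochs.json           {run: [[t0,t1],...], rest: [[t0,t1],...]}
    truth.json            ground-truth sidecar (synthetic sessions only)

All tables are tab-separated UTF-8 with '.' decimals; missing values are
empty fields. Times are seconds from session start.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataError, Epochs, LFPSignal, PositionTrace, SpikeTrain
from .synth import SynthSession, SynthTruth

_FLOAT_FMT = "%.6f"


def write_position(path, pos: PositionTrace) -> None:
    df = pd.DataFrame({"t": pos.t, "x": pos.x, "y": pos.y})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_position(path) -> PositionTrace:
    df = pd.read_csv(path, sep="\t")
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    t = df["t"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: non-monotone timestamps")
    return PositionTrace(t, df["x"].to_numpy(float), df["y"].to_numpy(float))


def write_spikes(dirpath, trains: list) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    meta = {}
    for tr in trains:
        n_ch = tr.amp.shape[1]
        n_f = tr.features.shape[1]
        cols = {"t": tr.t}
        for c in range(n_ch):
            cols[f"amp{c}"] = tr.amp[:, c]
        for c in range(n_f):
            cols[f"f{c}"] = tr.features[:, c]
        pd.DataFrame(cols).to_csv(d / f"{tr.unit_id}.tsv", sep="\t",
                                  index=False, float_format=_FLOAT_FMT)
        meta[tr.unit_id] = {"width_us": tr.width_us}
    with open(d / "units.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_spikes(dirpath) -> list:
    d = Path(dirpath)
    with open(d / "units.json") as fh:
        meta = json.load(fh)
    trains = []
    for uid in sorted(meta):
        df = pd.read_csv(d / f"{uid}.tsv", sep="\t")
        t = df["t"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            raise DataError(f"{uid}: non-monotone spike times")
        amp_cols = sorted(c for c in df.columns if c.startswith("amp"))
        f_cols = sorted(c for c in df.columns if c.startswith("f"))
        trains.append(SpikeTrain(
            uid, t, df[amp_cols].to_numpy(float),
            df[f_cols].to_numpy(float), float(meta[uid]["width_us"])))
    return trains


def write_lfp(path_bin, path_json, lfp: LFPSignal) -> None:
    peak = float(np.max(np.abs(lfp.samples))) or 1.0
    scale = peak / 32000.0
    raw = np.round(lfp.samples / scale).astype("<i2")
    raw.tofile(path_bin)
    with open(path_json, "w") as fh:
        json.dump({"fs_hz": lfp.fs_hz, "scale_uV": scale,
                   "channel_id": lfp.channel_id, "t0": lfp.t0}, fh, indent=1)


def read_lfp(path_bin, path_json, expect_fs_hz: float = None) -> LFPSignal:
    with open(path_json) as fh:
        meta = json.load(fh)
    if expect_fs_hz is not None and \
            abs(meta["fs_hz"] - expect_fs_hz) > 1e-6 * expect_fs_hz:
        raise DataError(f"LFP fs {meta['fs_hz']} != expected {expect_fs_hz}")
    raw = np.fromfile(path_bin, dtype="<i2")
    return LFPSignal(raw * meta["scale_uV"], meta["fs_hz"],
                     meta.get("channel_id", "lfp0"), meta.get("t0", 0.0))


def write_epochs(path, epochs: Epochs) -> None:
    with open(path, "w") as fh:
        json.dump({"run": [list(i) for i in epochs.run],
                   "rest": [list(i) for i in epochs.rest]}, fh, indent=1)


def read_epochs(path) -> Epochs:
    with open(path) as fh:
        d = json.load(fh)
    return Epochs(run=[tuple(i) for i in d.get("run", [])],
                  rest=[tuple(i) for i in d.get("rest", [])])


def write_truth(path, truth: SynthTruth) -> None:
    payload = {
        "units": truth.units,
        "ripple_intervals": [list(i) for i in truth.ripple_intervals],
        "spike_burst_id": {k: np.asarray(v).tolist()
                           for k, v in truth.spike_burst_id.items()},
        "spike_phase_deg": {k: np.round(np.asarray(v), 4).tolist()
                            for k, v in truth.spike_phase_deg.items()},
        "spike_injected": {k: np.asarray(v).astype(int).tolist()
                           for k, v in truth.spike_injected.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path) -> SynthTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SynthTruth(
        units=d["units"],
        ripple_intervals=[tuple(i) for i in d["ripple_intervals"]],
        spike_burst_id={k: np.asarray(v, int)
                        for k, v in d["spike_burst_id"].items()},
        spike_phase_deg={k: np.asarray(v, float)
                         for k, v in d["spike_phase_deg"].items()},
        spike_injected={k: np.asarray(v, bool)
                        for k, v in d["spike_injected"].items()})


def write_session(dirpath, session: SynthSession) -> None:
    """Write a (synthetic) session in the analysis input layout."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    write_position(d / "position.tsv", session.position)
    write_spikes(d / "spikes", session.spikes)
    write_lfp(d / "lfp.bin", d / "lfp.json", session.lfp)
    write_epochs(d / "epochs.json", session.epochs)
    if session.truth is not None:
        truth = session.truth
        truth.epochs = None
        write_truth(d / "truth.json", truth)


def read_session(dirpath, expect_fs_hz: float = None) -> dict:
    """Validated session bundle as a dict of streams."""
    d = Path(dirpath)
    for required in ("position.tsv", "spikes", "lfp.bin", "lfp.json",
                     "epochs.json"):
        if not (d / required).exists():
            raise DataError(f"missing session component: {required}")
    bundle = {
        "position": read_position(d / "position.tsv"),
        "spikes": read_spikes(d / "spikes"),
        "lfp": read_lfp(d / "lfp.bin", d / "lfp.json", expect_fs_hz),
        "epochs": read_epochs(d / "epochs.json"),
        "truth": None,
    }
    if (d / "truth.json").exists():
        bundle["truth"] = read_truth(d / "truth.json")
    return bundle
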