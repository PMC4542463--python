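"""Serialization of simulated recording sites.

A site is written as one JSON metadata file (site id, ground truth,
protocol, recording kind), a ``spikes.csv`` table (one row per spike,
tagged with the trial and condition), and — when analog data exist — a raw
float32 raster ``analog.f32`` with its layout described in the JSON header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (Epoch, ProtocolConfig, RecordingSite,
                         SiteGroundTruth, StimulusCondition)

_COND_FIELDS = ("frequency", "spl", "itd", "ear", "is_silent")


def _cond_dict(c: StimulusCondition) -> dict:
    return {k: getattr(c, k) for k in _COND_FIELDS}


def save_site(site: RecordingSite, directory) -> Path:
    """Write one site to ``directory`` (created if needed); returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows, analog_index = [], []
    waves = []
    for i, e in enumerate(site.epochs):
        base = dict(epoch_index=i, trial_index=e.trial_index, **_cond_dict(e.condition))
        for t in e.spike_times:
            rows.append(dict(base, spike_time_ms=float(t)))
        if e.analog is not None:
            analog_index.append(dict(base, n_samples=int(e.analog.size),
                                     sample_rate=e.sample_rate))
            waves.append(np.asarray(e.analog, dtype=np.float32))
    pd.DataFrame(rows, columns=["epoch_index", "trial_index", *_COND_FIELDS,
                                "spike_time_ms"]).to_csv(
        directory / "spikes.csv", index=False)

    meta = {
        "site_id": site.site_id,
        "recording_kind": site.recording_kind,
        "assigned_frequency": site.assigned_frequency,
        "frequency_provenance": site.frequency_provenance,
        "ground_truth": dataclasses.asdict(site.ground_truth)
        if site.ground_truth else None,
        "protocol": dataclasses.asdict(site.protocol) if site.protocol else None,
        "epochs": [dict(epoch_index=i, trial_index=e.trial_index,
                        **_cond_dict(e.condition))
                   for i, e in enumerate(site.epochs)],
        "analog_index": analog_index,
    }
    if waves:
        np.concatenate(waves).tofile(directory / "analog.f32")
    (directory / "site.json").write_text(json.dumps(meta, indent=1))
    return directory


def load_site(directory) -> RecordingSite:
    """Read a site previously written by :func:`save_site`."""
    directory = Path(directory)
    meta = json.loads((directory / "site.json").read_text())

    spikes = pd.read_csv(directory / "spikes.csv")
    spike_map: dict = {}
    if not spikes.empty:
        for idx, grp in spikes.groupby("epoch_index"):
            spike_map[int(idx)] = np.sort(grp["spike_time_ms"].to_numpy())

    analog_map: dict = {}
    if meta["analog_index"]:
        raster = np.fromfile(directory / "analog.f32", dtype=np.float32)
        pos = 0
        for entry in meta["analog_index"]:
            n = entry["n_samples"]
            analog_map[entry["epoch_index"]] = (raster[pos:pos + n],
                                                entry["sample_rate"])
            pos += n

    epochs = []
    for entry in meta["epochs"]:
        cond = StimulusCondition(**{k: entry[k] for k in _COND_FIELDS})
        i = entry["epoch_index"]
        analog, fs = analog_map.get(i, (None, 48000.0))
        epochs.append(Epoch(condition=cond,
                            spike_times=spike_map.get(i, np.empty(0)),
                            analog=analog, trial_index=entry["trial_index"],
                            sample_rate=fs))

    gt = meta["ground_truth"]
    proto = meta["protocol"]
    if proto:
        proto = dict(proto)
        proto["frequencies"] = tuple(proto["frequencies"])
    return RecordingSite(
        site_id=meta["site_id"], epochs=epochs,
        recording_kind=meta["recording_kind"],
        assigned_frequency=meta["assigned_frequency"],
        frequency_provenance=meta["frequency_provenance"],
        ground_truth=SiteGroundTruth(**gt) if gt else None,
        protocol=ProtocolConfig(**proto) if proto else None)
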