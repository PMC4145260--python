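"""Serialization helpers: waveform CSV/JSON, pulse JSON, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from imsde.waveforms import Axis, GradientLobe, LobeShape


def waveform_table(lobes, dt: float = 0.01, t_start: float = 0.0,
                   t_end: float | None = None) -> pd.DataFrame:
    """Sampled waveform as a table with columns time_ms, amplitude_mT_per_m, axis."""
    lobes = list(lobes)
    if t_end is None:
        t_end = max(l.end_time for l in lobes)
    t = np.arange(t_start, t_end + dt / 2.0, dt)
    frames = []
    for axis in sorted({l.axis for l in lobes}, key=lambda a: a.value):
        g = np.zeros_like(t)
        for lobe in lobes:
            if lobe.axis is axis:
                g += lobe.evaluate(t)
        frames.append(pd.DataFrame(
            {"time_ms": t, "amplitude_mT_per_m": g, "axis": axis.value}))
    return pd.concat(frames, ignore_index=True)


def write_waveform_csv(lobes, path, dt: float = 0.01) -> None:
    # %.17g keeps the samples bit-exact through a read back
    waveform_table(lobes, dt=dt).to_csv(path, index=False, float_format="%.17g")


def read_waveform_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def lobes_to_json(lobes) -> str:
    """Lossless parametric description of a lobe set."""
    return json.dumps(
        [
            {
                "shape": l.shape.value,
                "amplitude": l.amplitude,
                "ramp_time": l.ramp_time,
                "flat_time": l.flat_time,
                "start_time": l.start_time,
                "axis": l.axis.value,
            }
            for l in lobes
        ]
    )


def lobes_from_json(text: str) -> tuple:
    return tuple(
        GradientLobe(
            shape=LobeShape(d["shape"]), amplitude=d["amplitude"],
            ramp_time=d["ramp_time"], flat_time=d["flat_time"],
            start_time=d["start_time"], axis=Axis(d["axis"]),
        )
        for d in json.loads(text)
    )


def load_config(path) -> dict:
    """Read a YAML (or JSON; YAML is a superset) configuration file."""
    with open(Path(path)) as fh:
        return yaml.safe_load(fh) or {}
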