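"""Dataset CSV format, run configuration, and round-trip helpers.

Datasets are plain CSV with columns ``temperature_C, replicate, time_d,
count, frac_samp`` (temperatures experimentalist-facing in Celsius; all
internal math uses Kelvin).  Counts must be non-negative integers;
``frac_samp`` may vary per row (real experiments adapt the search effort to
the observed density).  A JSON sidecar ``<path>.meta.json`` carries the seed,
design and (for simulated data) the generating model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import ArrheniusModel, KB, T0_DEFAULT, celsius_to_kelvin, kelvin_to_celsius
from .simulate import Dataset, ExperimentalDesign, ObservedSeries

__all__ = [
    "DATASET_COLUMNS",
    "FORMAT_VERSION",
    "RunConfig",
    "read_dataset",
    "write_dataset",
]

DATASET_COLUMNS = ("temperature_C", "replicate", "time_d", "count", "frac_samp")
FORMAT_VERSION = "1"


@dataclass
class RunConfig:
    """Resolved settings of a run; round-trips losslessly through YAML."""

    seed: int = 0
    T0: float = T0_DEFAULT
    kB: float = KB
    dt: float = 0.0125
    n_iter: int = 20000
    burn_frac: float = 0.5
    n_keep: int = 1000
    mle_starts: int = 3
    reps_per_cell: int = 20
    format_version: str = FORMAT_VERSION
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _meta_path(path: str) -> str:
    return str(path) + ".meta.json"


def write_dataset(dataset: Dataset, path: str) -> None:
    """Write a dataset as CSV plus a JSON metadata sidecar."""
    rows = []
    for s in dataset.series:
        for t, c, f in zip(s.times, s.counts, s.frac_samp):
            rows.append(
                {
                    "temperature_C": round(kelvin_to_celsius(s.temperature), 6),
                    "replicate": s.replicate,
                    "time_d": t,
                    "count": int(c),
                    "frac_samp": f,
                }
            )
    pd.DataFrame(rows, columns=list(DATASET_COLUMNS)).to_csv(path, index=False)
    meta: dict = {
        "format_version": dataset.format_version,
        "seed": dataset.seed,
        "n0": dataset.n0,
        "N": dataset.N,
    }
    if dataset.design is not None:
        d = dataset.design
        meta["design"] = {
            "temperatures_C": [kelvin_to_celsius(t) for t in d.temperatures],
            "reps": d.reps,
            "sample_times": list(d.sample_times),
            "frac_samp": d.frac_samp,
            "n0": d.n0,
            "horizon": d.horizon,
        }
    if dataset.truth is not None:
        m = dataset.truth
        meta["truth"] = {
            "theta01": m.theta01,
            "theta02": m.theta02,
            "theta03": m.theta03,
            "e_a": list(m.e_a_triple),
            "T0": m.T0,
            "N": m.N,
        }
    with open(_meta_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_dataset(path: str) -> Dataset:
    """Read and validate a dataset CSV (with optional metadata sidecar).

    Malformed rows are reported with their 1-based data row number.
    """
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    problems = []
    counts = df["count"]
    int_ok = counts.notna() & (np.mod(pd.to_numeric(counts, errors="coerce"), 1) == 0)
    for i in df.index[~int_ok]:
        problems.append(f"row {i + 1}: count {counts[i]!r} is not an integer")
    for i in df.index[int_ok & (pd.to_numeric(counts, errors="coerce") < 0)]:
        problems.append(f"row {i + 1}: count {counts[i]!r} is negative")
    fr = pd.to_numeric(df["frac_samp"], errors="coerce")
    for i in df.index[~((fr > 0) & (fr <= 1))]:
        problems.append(f"row {i + 1}: frac_samp {df['frac_samp'][i]!r} not in (0, 1]")
    if problems:
        raise ValueError(f"{path}: invalid rows:\n" + "\n".join(problems))

    series = []
    for (t_c, rep), g in df.groupby(["temperature_C", "replicate"], sort=True):
        g = g.sort_values("time_d")
        series.append(
            ObservedSeries(
                temperature=celsius_to_kelvin(float(t_c)),
                replicate=int(rep),
                times=g["time_d"].to_numpy(dtype=float),
                counts=g["count"].to_numpy(dtype=np.int64),
                frac_samp=g["frac_samp"].to_numpy(dtype=float),
            )
        )
    design = truth = None
    seed = n0 = None
    N = 15000
    meta_file = _meta_path(path)
    try:
        with open(meta_file) as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = None
    if meta:
        seed = meta.get("seed")
        n0 = meta.get("n0")
        N = meta.get("N", N)
        if "design" in meta:
            d = meta["design"]
            design = ExperimentalDesign(
                temperatures=tuple(celsius_to_kelvin(t) for t in d["temperatures_C"]),
                reps=d["reps"],
                sample_times=tuple(d["sample_times"]),
                frac_samp=d["frac_samp"],
                n0=d["n0"],
                horizon=d["horizon"],
            )
        if "truth" in meta:
            m = meta["truth"]
            truth = ArrheniusModel(
                theta01=m["theta01"], theta02=m["theta02"], theta03=m["theta03"],
                e_a=tuple(m["e_a"]), T0=m["T0"], N=m["N"],
            )
    return Dataset(series=series, design=design, truth=truth, seed=seed,
                   n0=n0, N=N)
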