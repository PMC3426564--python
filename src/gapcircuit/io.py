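"""Readers and writers for profile and parameter tables, plus run manifests.

All tables are delimited text (comma-separated, dot decimal, UTF-8, header
row).  Profile tables are long format with columns genotype, gene,
time_class, position_EL, level; rows for the external regulators (bcd, cad,
tll) carry the anchor profiles and rows with time_class C12 carry the hb
initial profile.  Parameter tables follow the one-row-per-target-gene
layout: T columns for the gap regulators, E columns for the external
inputs, then h, R, D, lam.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, OBS_COLUMNS
from .model import (DEFAULT_H, DEFAULT_ROSTER, CircuitParameters,
                    CircuitError, ExternalInputSeries, GeneRoster, MAX_LEVEL)
from .simulate import DEFAULT_SCHEDULE, TIME_CLASSES

__all__ = ["read_profiles", "write_profiles", "read_params", "write_params",
           "RunManifest", "write_manifest"]

_EXTERNAL_TIME_CLASSES = ("C12",) + TIME_CLASSES


def write_profiles(dataset: ExpressionDataset, path) -> Path:
    """Write a dataset (observations, hb C12 profile, external anchors) as
    one long-format CSV."""
    path = Path(path)
    frames = [dataset.observations[list(OBS_COLUMNS)]]
    frames.append(pd.DataFrame({
        "genotype": dataset.wt_label, "gene": "hb", "time_class": "C12",
        "position_EL": dataset.hb_c12_positions,
        "level": dataset.hb_c12_levels}))
    ext = dataset.external
    anchor_classes = _EXTERNAL_TIME_CLASSES
    if ext.times.size != len(anchor_classes):
        raise CircuitError("external series does not match the standard "
                           "anchor schedule")
    for e, name in enumerate(dataset.roster.external_inputs):
        for k, tc in enumerate(anchor_classes):
            frames.append(pd.DataFrame({
                "genotype": dataset.wt_label, "gene": name,
                "time_class": tc, "position_EL": ext.positions,
                "level": ext.values[e, k]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_profiles(path, roster: GeneRoster = DEFAULT_ROSTER,
                  wt_label: str = "wt",
                  mut_label: str = "Kr_null") -> ExpressionDataset:
    """Read a long-format profile CSV back into an ExpressionDataset.

    Rows whose gene is an external input become the anchor profiles; hb
    rows at time class C12 become the initial condition; everything else is
    an observation.  Levels are validated to [0, 255] and unknown gene
    labels are rejected.
    """
    df = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise CircuitError(f"profile table lacks columns {sorted(missing)}")
    known = set(roster.gap_genes) | set(roster.external_inputs)
    bad = set(df["gene"].unique()) - known
    if bad:
        raise CircuitError(f"unknown gene label(s) {sorted(bad)}")
    bad_level = df[(df["level"] < 0) | (df["level"] > MAX_LEVEL)]
    if len(bad_level):
        raise CircuitError(
            f"level outside [0, {MAX_LEVEL:g}] at row "
            f"{bad_level.index[0]}")

    is_ext = df["gene"].isin(roster.external_inputs)
    is_init = (df["gene"] == "hb") & (df["time_class"] == "C12")
    obs = df[~is_ext & ~is_init].reset_index(drop=True)
    init = df[is_init].sort_values("position_EL")
    if not len(init):
        raise CircuitError("profile table lacks the hb C12 initial profile")

    ext_rows = df[is_ext]
    anchor_classes = _EXTERNAL_TIME_CLASSES
    times = np.concatenate([[-6.2], DEFAULT_SCHEDULE.comparison_times])
    positions = np.sort(ext_rows["position_EL"].unique())
    values = np.empty((roster.n_external, times.size, positions.size))
    for e, name in enumerate(roster.external_inputs):
        for k, tc in enumerate(anchor_classes):
            sub = ext_rows[(ext_rows["gene"] == name)
                           & (ext_rows["time_class"] == tc)]
            if len(sub) != positions.size:
                raise CircuitError(
                    f"external input {name} lacks anchors at {tc}")
            sub = sub.sort_values("position_EL")
            values[e, k] = sub["level"].to_numpy(float)
    external = ExternalInputSeries(times, positions, values, roster)
    return ExpressionDataset(obs, external,
                             init["position_EL"].to_numpy(float),
                             init["level"].to_numpy(float),
                             wt_label=wt_label, mut_label=mut_label,
                             roster=roster)


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

def write_params(params: CircuitParameters, path) -> Path:
    """One row per target gene; columns T_<regulator>, E_<input>, h, R, D,
    lam.  Full float precision (round-trips exactly)."""
    path = Path(path)
    roster = params.roster
    cols = {"gene": list(roster.gap_genes)}
    for b, reg in enumerate(roster.gap_genes):
        cols[f"T_{reg}"] = params.T[:, b]
    for e, reg in enumerate(roster.external_inputs):
        cols[f"E_{reg}"] = params.E[:, e]
    cols.update(h=params.h, R=params.R, D=params.D, lam=params.lam)
    pd.DataFrame(cols).to_csv(path, index=False,
                              float_format=lambda v: repr(float(v)))
    return path


def read_params(path, roster: GeneRoster = DEFAULT_ROSTER
                ) -> CircuitParameters:
    """Read a parameter table; an absent h column defaults to -3.5."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df["gene"]) != list(roster.gap_genes):
        raise CircuitError("parameter table rows must be the gap genes in "
                           f"order {roster.gap_genes}")
    T = np.column_stack([df[f"T_{r}"] for r in roster.gap_genes])
    E = np.column_stack([df[f"E_{r}"] for r in roster.external_inputs])
    h = df["h"].to_numpy(float) if "h" in df.columns else \
        np.full(roster.n_gap, DEFAULT_H)
    lam = df["lam"].to_numpy(float)
    if np.any(lam <= 0):
        raise CircuitError("decay rates in a parameter table must be "
                           "positive (finite protein half-life)")
    return CircuitParameters(T=T, E=E, h=h, R=df["R"].to_numpy(float),
                             D=df["D"].to_numpy(float), lam=lam,
                             roster=roster)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance of one pipeline run: command, config hash, seed, paths."""

    command: str
    seed: int
    inputs: list
    outputs: list
    config: dict
    package_version: str = ""
    timestamp: str = ""
    config_hash: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        if not self.package_version:
            from . import __version__
            self.package_version = __version__
        if not self.config_hash:
            blob = json.dumps(self.config, sort_keys=True, default=str)
            self.config_hash = hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(manifest: RunManifest, outdir) -> Path:
    """Write the single manifest.json of an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, default=str))
    return path
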