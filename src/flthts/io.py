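"""File formats and run configuration.

Everything on disk is plain text: waveforms as long- or wide-format CSV,
plate maps as CSV with a JSON-encoded planted-effect column, configuration
as YAML, run summaries as JSON.  Well names follow rows A–AF (32 rows) by
columns 1–48 for 1536-well plates and A–P / 1–24 for 384-well plates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .irf import IRFModel, TimeGrid
from .simulate import DecayGroundTruth, NoiseSpec, PlateLayout, SimulatedPlate

__all__ = [
    "RunConfig",
    "VALID_ROLES",
    "read_plate_map",
    "write_plate_map",
    "write_waveforms_long",
    "read_waveforms_long",
    "write_waveforms_wide",
    "read_waveforms_wide",
    "write_plate",
    "read_plate",
    "load_config",
    "save_config",
]

VALID_ROLES = ("dmso", "compound", "tool")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, layout and simulation settings for one pipeline run.

    Defaults are the screen's operating point: 3 SD interference flag,
    5 SD hit threshold (7 SD reported alongside), 3 SD counter-screen,
    rZ' acceptance gate at 0.5, second-channel spectral fraction 0.43.
    """

    irf: IRFModel = field(default_factory=IRFModel)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    layout: PlateLayout = field(default_factory=PlateLayout)
    truth: DecayGroundTruth = field(default_factory=DecayGroundTruth)
    flag_threshold_sd: float = 3.0
    hit_threshold_sd: float = 5.0
    counter_threshold_sd: float = 3.0
    rzprime_gate: float = 0.5
    n_components: int = 2
    tool_dtau_ns: float = -0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flag_threshold_sd", "hit_threshold_sd", "counter_threshold_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "irf": {
                "shape": self.irf.shape,
                "center": self.irf.center,
                "width": self.irf.width,
                "grid": {"start": self.irf.grid.start, "step": self.irf.grid.step,
                         "n": self.irf.grid.n},
            },
            "noise": dataclasses.asdict(self.noise),
            "layout": {
                "format": self.layout.format,
                "n_compounds": self.layout.n_compounds,
                "tool_cols": list(self.layout.tool_cols),
            },
            "truth": {
                "x": list(self.truth.x),
                "tau_ns": list(self.truth.tau_ns),
                "channel2_fraction": self.truth.channel2_fraction,
                "total_intensity": self.truth.total_intensity,
            },
            "flag_threshold_sd": self.flag_threshold_sd,
            "hit_threshold_sd": self.hit_threshold_sd,
            "counter_threshold_sd": self.counter_threshold_sd,
            "rzprime_gate": self.rzprime_gate,
            "n_components": self.n_components,
            "tool_dtau_ns": self.tool_dtau_ns,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw: dict = {}
        if "irf" in d:
            g = d["irf"].get("grid", {})
            kw["irf"] = IRFModel(
                shape=d["irf"].get("shape", "gaussian"),
                center=d["irf"].get("center", 10.0),
                width=d["irf"].get("width", 1.0),
                grid=TimeGrid(**g) if g else TimeGrid(),
            )
        if "noise" in d:
            kw["noise"] = NoiseSpec(**d["noise"])
        if "layout" in d:
            lay = dict(d["layout"])
            lay["tool_cols"] = tuple(lay.get("tool_cols") or ())
            kw["layout"] = PlateLayout(**lay)
        if "truth" in d:
            tr = dict(d["truth"])
            tr["x"] = tuple(tr["x"])
            tr["tau_ns"] = tuple(tr["tau_ns"])
            kw["truth"] = DecayGroundTruth(**tr)
        for name in (
            "flag_threshold_sd", "hit_threshold_sd", "counter_threshold_sd",
            "rzprime_gate", "n_components", "tool_dtau_ns", "seed",
        ):
            if name in d:
                kw[name] = d[name]
        return cls(**kw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# plate maps


def write_plate_map(pmap: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("well", "role", "compound_id", "concentration_molar", "planted_effect")
            if c in pmap.columns]
    pmap[cols].to_csv(path, index=False)


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate-map CSV (columns: well, role, compound_id, ...)."""
    pmap = pd.read_csv(path, dtype={"well": str}, keep_default_na=False)
    missing = {"well", "role"} - set(pmap.columns)
    if missing:
        raise ValueError(f"plate map is missing required columns: {sorted(missing)}")
    dupes = pmap["well"][pmap["well"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate well ids in plate map: {sorted(set(dupes))}")
    bad = set(pmap["role"]) - set(VALID_ROLES)
    if bad:
        raise ValueError(
            f"unknown role(s) {sorted(bad)}; valid roles are {list(VALID_ROLES)}"
        )
    if "compound_id" not in pmap.columns:
        pmap["compound_id"] = ""
    return pmap


# ---------------------------------------------------------------------------
# waveform tables


def write_waveforms_long(plate: SimulatedPlate, path: str | Path) -> None:
    """Long format: one row per (well, channel, time point)."""
    t = plate.irf.grid.times()
    frames = []
    for ch, arr in (("Ch1", plate.ch1), ("Ch2", plate.ch2)):
        n_wells = arr.shape[0]
        frames.append(
            pd.DataFrame(
                {
                    "well": np.repeat(plate.wells, t.size),
                    "channel": ch,
                    "time_ns": np.tile(t, n_wells),
                    "intensity": arr.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_waveforms_long(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well": str})
    missing = {"well", "channel", "time_ns", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"waveform table is missing columns: {sorted(missing)}")
    return df


def write_waveforms_wide(plate: SimulatedPlate, path: str | Path, channel: str = "Ch1") -> None:
    """Wide format: one row per well, one column per time point ('t<ns>')."""
    t = plate.irf.grid.times()
    arr = plate.ch1 if channel == "Ch1" else plate.ch2
    df = pd.DataFrame(arr, columns=[f"t{ti:.4g}" for ti in t])
    df.insert(0, "well", plate.wells)
    df.to_csv(path, index=False)


def read_waveforms_wide(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Returns (wells, time axis in ns, intensity array of shape (wells, time))."""
    df = pd.read_csv(path, dtype={"well": str})
    tcols = [c for c in df.columns if c.startswith("t") and c != "well"]
    t = np.array([float(c[1:]) for c in tcols])
    return list(df["well"]), t, df[tcols].to_numpy(float)


def write_plate(plate: SimulatedPlate, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated plate as plate_map.csv + ch1.csv + ch2.csv (+ meta)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "plate_map": out / "plate_map.csv",
        "ch1": out / "ch1.csv",
        "ch2": out / "ch2.csv",
        "meta": out / "meta.json",
    }
    write_plate_map(plate.plate_map, paths["plate_map"])
    write_waveforms_wide(plate, paths["ch1"], channel="Ch1")
    write_waveforms_wide(plate, paths["ch2"], channel="Ch2")
    meta = {
        "irf": {"shape": plate.irf.shape, "center": plate.irf.center, "width": plate.irf.width,
                "grid": {"start": plate.irf.grid.start, "step": plate.irf.grid.step,
                         "n": plate.irf.grid.n}},
        "seed": plate.seed,
        "tool_dtau_ns": plate.tool_dtau_ns,
        "truth": {"x": list(plate.truth.x), "tau_ns": list(plate.truth.tau_ns),
                  "channel2_fraction": plate.truth.channel2_fraction,
                  "total_intensity": plate.truth.total_intensity},
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_plate(in_dir: str | Path) -> SimulatedPlate:
    """Reassemble a SimulatedPlate written by :func:`write_plate`."""
    d = Path(in_dir)
    meta = json.loads((d / "meta.json").read_text())
    irf = IRFModel(
        shape=meta["irf"]["shape"],
        center=meta["irf"]["center"],
        width=meta["irf"]["width"],
        grid=TimeGrid(**meta["irf"]["grid"]),
    )
    pmap = read_plate_map(d / "plate_map.csv")
    wells1, _, ch1 = read_waveforms_wide(d / "ch1.csv")
    wells2, _, ch2 = read_waveforms_wide(d / "ch2.csv")
    if wells1 != list(pmap["well"]) or wells2 != list(pmap["well"]):
        raise ValueError("waveform well order does not match the plate map")
    tr = meta["truth"]
    truth = DecayGroundTruth(
        x=tuple(tr["x"]), tau_ns=tuple(tr["tau_ns"]),
        channel2_fraction=tr["channel2_fraction"], total_intensity=tr["total_intensity"],
    )
    return SimulatedPlate(
        plate_map=pmap, ch1=ch1, ch2=ch2, irf=irf, truth=truth,
        tool_dtau_ns=meta["tool_dtau_ns"], seed=meta["seed"],
    )
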