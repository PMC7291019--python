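"""Synthetic two-channel lifetime screens and functional-assay datasets.

This module generates every input the analysis pipeline consumes, with the
statistical structure of a live-cell lifetime-FRET screen:

* per-well two-channel decay waveforms — a bi-exponential donor decay
  (~2 ns mean lifetime) convolved with the IRF, with the second emission
  channel a fixed spectral fraction (default 0.43) of the first;
* full 1536- or 384-well plates with DMSO vehicle controls in the outer
  column pairs, optional tool-compound control wells, and planted effects
  (lifetime-shifting hits and fluorescent interferers) recorded as ground
  truth for later scoring;
* Hill-shaped concentration-response datasets (pCa or molar concentration
  mode) and Ca-uptake fluorescence time courses.

Shot noise is modelled as additive Gaussian with sigma proportional to the
square root of the expected signal; the default per-well intensity is
calibrated so that the SD of fitted mean lifetimes across vehicle wells is
below 10 ps, the instrument precision the pipeline assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .decay import Waveform, convolve_model
from .irf import DEFAULT_IRF, IRFModel

__all__ = [
    "NoiseSpec",
    "Contaminant",
    "DecayGroundTruth",
    "PlantedEffect",
    "PlateLayout",
    "SimulatedPlate",
    "HillGroundTruth",
    "DEFAULT_DMSO_TRUTH",
    "PCA_GRID",
    "ATPASE_CONTROL_TRUTH",
    "ATPASE_FUSION_TRUTH",
    "TG_CRC_TRUTH",
    "TG_DOSE_GRID_M",
    "hill_curve",
    "row_name",
    "well_name",
    "simulate_waveform",
    "simulate_plate",
    "simulate_hill_dataset",
    "simulate_uptake_trace",
]

# Default per-well integrated intensity (total counts summed over the trace).
# Chosen so that shot noise propagates to a fitted mean-lifetime SD of ~6-7 ps
# for the default ~2 ns bi-exponential decay — inside the 10 ps precision
# envelope of subnanosecond direct-waveform-recording plate readers.
DEFAULT_TOTAL_INTENSITY = 1.0e6


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise model.

    kind
        ``"none"``, ``"gaussian"`` (additive, constant ``sigma`` counts), or
        ``"shot"`` (additive Gaussian with sigma = ``shot_scale`` * sqrt(signal),
        the Gaussian limit of Poisson counting noise) or ``"poisson"``
        (exact Poisson counts).
    """

    kind: str = "shot"
    sigma: float = 0.0
    shot_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "shot", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def apply(self, model: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return model.copy()
        if self.kind == "gaussian":
            return model + rng.normal(0.0, self.sigma, model.shape)
        if self.kind == "poisson":
            return rng.poisson(np.clip(model, 0, None)).astype(float)
        sd = self.shot_scale * np.sqrt(np.clip(model, 0, None))
        return model + rng.normal(0.0, 1.0, model.shape) * sd


@dataclass(frozen=True)
class Contaminant:
    """Fluorescent-compound component: an extra exponential added per channel.

    ``frac_ch1``/``frac_ch2`` are its integrated intensity as a fraction of
    the clean Ch1 signal, so unequal fractions perturb the two-channel ratio
    while any nonzero fraction also perturbs the fitted lifetime.
    """

    frac_ch1: float = 0.0
    frac_ch2: float = 0.1
    tau_ns: float = 3.5

    def __post_init__(self) -> None:
        if not (0 <= self.frac_ch1 < 1 and 0 <= self.frac_ch2 < 1):
            raise ValueError("contaminant fractions must lie in [0, 1)")
        if self.tau_ns <= 0:
            raise ValueError("contaminant lifetime must be > 0")


@dataclass(frozen=True)
class DecayGroundTruth:
    """True per-well decay parameters for the simulator.

    Amplitude fractions must sum to 1; ``channel2_fraction`` is the spectral
    fraction of donor emission falling in the second detection channel.
    ``total_intensity`` is the summed Ch1 counts over the trace.
    """

    x: tuple[float, ...] = (0.6, 0.4)
    tau_ns: tuple[float, ...] = (2.5, 1.25)
    channel2_fraction: float = 0.43
    total_intensity: float = DEFAULT_TOTAL_INTENSITY
    contaminant: Contaminant | None = None

    def __post_init__(self) -> None:
        if len(self.x) != len(self.tau_ns):
            raise ValueError("x and tau_ns must have the same length")
        if abs(sum(self.x) - 1.0) > 1e-9:
            raise ValueError(f"amplitude fractions must sum to 1, got {sum(self.x)}")
        if any(tau <= 0 for tau in self.tau_ns):
            raise ValueError("all lifetimes must be > 0")
        if not 0 < self.channel2_fraction < 1:
            raise ValueError("channel2_fraction must lie in (0, 1)")

    @property
    def mean_tau_ns(self) -> float:
        return float(np.dot(self.x, self.tau_ns))

    def shifted(self, dtau_ns: float) -> "DecayGroundTruth":
        """Truth with every lifetime shifted by ``dtau_ns`` (mean shifts by the same)."""
        new_tau = tuple(tau + dtau_ns for tau in self.tau_ns)
        if any(tau <= 0 for tau in new_tau):
            raise ValueError(f"lifetime shift {dtau_ns} ns drives a component negative")
        return replace(self, tau_ns=new_tau)


DEFAULT_DMSO_TRUTH = DecayGroundTruth()  # mean lifetime 2.0 ns


def _check_coverage(irf: IRFModel, truth: DecayGroundTruth) -> None:
    window = irf.grid.end - irf.center
    longest = max(truth.tau_ns)
    if window < 5.0 * longest:
        raise ValueError(
            f"time grid covers {window:.1f} ns after the IRF centre, less than "
            f"5x the longest lifetime ({longest:.2f} ns); extend the grid"
        )


def simulate_waveform(
    truth: DecayGroundTruth,
    irf: IRFModel = DEFAULT_IRF,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | np.random.Generator = 0,
) -> tuple[Waveform, Waveform]:
    """Simulate one well's (Ch1, Ch2) waveform pair.

    Ch1 is the IRF-convolved multi-exponential scaled so its noiseless sum
    equals ``truth.total_intensity``; Ch2 is ``channel2_fraction`` times the
    same decay model, plus any contaminant component, noised independently.
    In the noiseless contaminant-free case the integrated Ch2/Ch1 ratio
    equals ``channel2_fraction`` exactly.
    """
    _check_coverage(irf, truth)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = irf.grid.times()

    shape = convolve_model(np.asarray(truth.x), np.asarray(truth.tau_ns), irf)
    scale = truth.total_intensity / shape.sum()
    ch1 = scale * shape
    ch2 = truth.channel2_fraction * ch1

    if truth.contaminant is not None:
        c = truth.contaminant
        cshape = convolve_model(np.array([1.0]), np.array([c.tau_ns]), irf)
        cshape = cshape / cshape.sum() * truth.total_intensity
        ch1 = ch1 + c.frac_ch1 * cshape
        ch2 = ch2 + c.frac_ch2 * cshape

    y1 = noise.apply(ch1, rng)
    y2 = noise.apply(ch2, rng)
    return (
        Waveform(time_ns=t, intensity=y1, channel="Ch1"),
        Waveform(time_ns=t, intensity=y2, channel="Ch2"),
    )


# ---------------------------------------------------------------------------
# plates


def row_name(i: int) -> str:
    """Row index -> letter label (0 -> 'A', 25 -> 'Z', 26 -> 'AA', 31 -> 'AF')."""
    if i < 26:
        return chr(ord("A") + i)
    return "A" + chr(ord("A") + i - 26)


def well_name(row: int, col: int) -> str:
    return f"{row_name(row)}{col + 1}"


@dataclass(frozen=True)
class PlateLayout:
    """Plate geometry and role assignment.

    1536-well plates are 32 rows x 48 columns with DMSO vehicle controls in
    columns 1, 2, 47 and 48; 384-well plates are 16 x 24 with controls in
    columns 1, 2, 23 and 24.  ``tool_cols`` marks control columns carrying a
    saturating tool compound (e.g. thapsigargin) instead of vehicle.
    """

    format: int = 1536
    n_compounds: int | None = None
    tool_cols: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.format not in (1536, 384):
            raise ValueError("plate format must be 1536 or 384")
        bad = set(self.tool_cols) - set(self.control_cols)
        if bad:
            raise ValueError(f"tool columns {sorted(bad)} are not control columns")

    @property
    def shape(self) -> tuple[int, int]:
        return (32, 48) if self.format == 1536 else (16, 24)

    @property
    def control_cols(self) -> tuple[int, ...]:
        ncols = self.shape[1]
        return (1, 2, ncols - 1, ncols)

    def build_map(self) -> pd.DataFrame:
        """Well map with columns well, row, col, role, compound_id."""
        nrows, ncols = self.shape
        records = []
        dmso_cols = set(self.control_cols) - set(self.tool_cols)
        compound_slots = [
            (r, c)
            for c in range(1, ncols + 1)
            if c not in self.control_cols
            for r in range(nrows)
        ]
        n_cmpd = len(compound_slots) if self.n_compounds is None else self.n_compounds
        if n_cmpd > len(compound_slots):
            raise ValueError(f"{n_cmpd} compounds do not fit in {len(compound_slots)} wells")
        filled = {slot: f"C{i + 1:04d}" for i, slot in enumerate(compound_slots[:n_cmpd])}
        for r in range(nrows):
            for c in range(1, ncols + 1):
                if c in dmso_cols:
                    role, cid = "dmso", ""
                elif c in self.tool_cols:
                    role, cid = "tool", ""
                elif (r, c) in filled:
                    role, cid = "compound", filled[(r, c)]
                else:
                    role, cid = "dmso", ""  # unused wells receive vehicle
                records.append(
                    {"well": well_name(r, c - 1), "row": r, "col": c,
                     "role": role, "compound_id": cid}
                )
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effect planted in one compound well."""

    kind: str  # "shift" | "contaminant"
    dtau_ns: float = 0.0
    contaminant: Contaminant | None = None

    def to_json(self) -> str:
        d: dict = {"kind": self.kind}
        if self.kind == "shift":
            d["dtau_ns"] = self.dtau_ns
        elif self.contaminant is not None:
            c = self.contaminant
            d.update(frac_ch1=c.frac_ch1, frac_ch2=c.frac_ch2, tau_ns=c.tau_ns)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "PlantedEffect":
        d = json.loads(s)
        if d["kind"] == "shift":
            return cls(kind="shift", dtau_ns=d["dtau_ns"])
        return cls(
            kind="contaminant",
            contaminant=Contaminant(d["frac_ch1"], d["frac_ch2"], d["tau_ns"]),
        )


@dataclass(frozen=True)
class SimulatedPlate:
    """One simulated plate: well map, stacked waveforms, and ground truth."""

    plate_map: pd.DataFrame  # well, row, col, role, compound_id, planted_effect
    ch1: np.ndarray  # (n_wells, n_time)
    ch2: np.ndarray
    irf: IRFModel
    truth: DecayGroundTruth
    tool_dtau_ns: float
    seed: int

    @property
    def wells(self) -> list[str]:
        return list(self.plate_map["well"])

    def waveform(self, well: str, channel: str = "Ch1") -> Waveform:
        idx = self.plate_map.index[self.plate_map["well"] == well]
        if len(idx) == 0:
            raise KeyError(f"no well {well!r} on this plate")
        arr = self.ch1 if channel == "Ch1" else self.ch2
        return Waveform(
            time_ns=self.irf.grid.times(),
            intensity=arr[idx[0]],
            channel=channel,
            well=well,
        )


def simulate_plate(
    layout: PlateLayout = PlateLayout(),
    effects: dict[str, PlantedEffect] | None = None,
    irf: IRFModel = DEFAULT_IRF,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    truth: DecayGroundTruth = DEFAULT_DMSO_TRUTH,
    tool_dtau_ns: float = -0.15,
) -> SimulatedPlate:
    """Simulate a full plate with planted effects.

    ``effects`` maps well names (compound wells only) to a PlantedEffect;
    vehicle wells share ``truth`` apart from noise, and tool wells (if the
    layout defines any) get ``truth`` shifted by ``tool_dtau_ns`` — the
    lifetime drop a saturating FRET-increasing tool compound produces.
    Deterministic for a given seed.
    """
    effects = effects or {}
    pmap = layout.build_map()
    roles = dict(zip(pmap["well"], pmap["role"]))
    for w in effects:
        if w not in roles:
            raise KeyError(f"planted effect refers to unknown well {w!r}")
        if roles[w] != "compound":
            raise ValueError(f"planted effect assigned to {roles[w]} control well {w}")

    rng = np.random.default_rng(seed)
    n_t = irf.grid.n
    ch1 = np.empty((len(pmap), n_t))
    ch2 = np.empty((len(pmap), n_t))
    planted = []
    for i, row in enumerate(pmap.itertuples(index=False)):
        w_truth = truth
        eff = effects.get(row.well)
        if row.role == "tool":
            w_truth = truth.shifted(tool_dtau_ns)
        elif eff is not None:
            if eff.kind == "shift":
                w_truth = truth.shifted(eff.dtau_ns)
            else:
                w_truth = replace(truth, contaminant=eff.contaminant)
        w1, w2 = simulate_waveform(w_truth, irf, noise, seed=rng)
        ch1[i], ch2[i] = w1.intensity, w2.intensity
        planted.append(eff.to_json() if eff is not None else "")
    pmap = pmap.assign(planted_effect=planted)
    return SimulatedPlate(
        plate_map=pmap, ch1=ch1, ch2=ch2, irf=irf, truth=truth,
        tool_dtau_ns=tool_dtau_ns, seed=seed,
    )


# ---------------------------------------------------------------------------
# functional assays


@dataclass(frozen=True)
class HillGroundTruth:
    """True Hill-curve parameters for a concentration-response simulation.

    ``midpoint`` is the pCa50 (pCa mode) or the EC50 in molar (concentration
    mode); ``n_hill`` the Hill coefficient; plateaus in assay units.
    """

    midpoint: float
    n_hill: float = 2.0
    lower: float = 0.0
    upper: float = 1.0
    x_mode: str = "pCa"  # or "concentration"
    n_replicates: int = 8
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_hill <= 0:
            raise ValueError("Hill coefficient must be > 0")
        if self.upper <= self.lower:
            raise ValueError("upper plateau must exceed lower plateau")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.x_mode not in ("pCa", "concentration"):
            raise ValueError("x_mode must be 'pCa' or 'concentration'")


def hill_curve(x: np.ndarray, midpoint: float, n_hill: float, lower: float,
               upper: float, x_mode: str = "pCa") -> np.ndarray:
    """Evaluate the Hill model.

    pCa mode: activity falls sigmoidally with pCa (rises with [Ca2+]),
    midpoint at pCa50.  Concentration mode: standard Hill in x (molar),
    midpoint at EC50.
    """
    x = np.asarray(x, dtype=float)
    if x_mode == "pCa":
        return lower + (upper - lower) / (1.0 + 10.0 ** (n_hill * (x - midpoint)))
    return lower + (upper - lower) / (1.0 + (midpoint / x) ** n_hill)


def simulate_hill_dataset(
    truth: HillGroundTruth,
    x_values: np.ndarray,
    seed: int = 0,
    assay: str = "",
) -> pd.DataFrame:
    """Replicated Hill responses with iid Gaussian noise.

    Returns the long-format table the dose-response reader consumes:
    columns assay, x_value, x_mode, replicate, response.  Warns when the
    grid never crosses the midpoint (the midpoint is then unidentifiable).
    """
    x = np.asarray(x_values, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 distinct x values")
    if x.min() > truth.midpoint or x.max() < truth.midpoint:
        import warnings

        warnings.warn(
            "x grid lies entirely on one side of the midpoint; "
            "the half-max point will be poorly identified",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    mu = hill_curve(x, truth.midpoint, truth.n_hill, truth.lower, truth.upper, truth.x_mode)
    rows = []
    for rep in range(truth.n_replicates):
        y = mu + rng.normal(0.0, truth.noise_sd, x.size)
        for xi, yi in zip(x, y):
            rows.append(
                {"assay": assay, "x_value": xi, "x_mode": truth.x_mode,
                 "replicate": rep, "response": yi}
            )
    return pd.DataFrame.from_records(rows)


# Canonical functional-assay conditions used throughout examples and tests.
# Ca-ATPase activity vs pCa: 13-point grid spanning both plateaus, n=8
# replicates, normalized activity 0..1.  Noise SDs are set so the refitted
# pCa50 standard errors land on the assay's reported precision (~0.04 pCa
# units for the pump-only control, ~0.03 for the pump-inhibitor fusion).
PCA_GRID = np.linspace(7.8, 5.0, 13)
ATPASE_CONTROL_TRUTH = HillGroundTruth(
    midpoint=6.62, n_hill=2.0, x_mode="pCa", n_replicates=8, noise_sd=0.155
)
ATPASE_FUSION_TRUTH = HillGroundTruth(
    midpoint=6.38, n_hill=2.0, x_mode="pCa", n_replicates=8, noise_sd=0.115
)
# Thapsigargin lifetime-detected FRET CRC: the response is the magnitude of
# the lifetime drop (ns) at each dose; per-well lifetime noise ~8 ps.
TG_CRC_TRUTH = HillGroundTruth(
    midpoint=7.5e-9, n_hill=1.0, lower=0.0, upper=0.080,
    x_mode="concentration", n_replicates=3, noise_sd=0.008,
)
TG_DOSE_GRID_M = np.logspace(-10.0, -6.5, 9)


def simulate_uptake_trace(
    rate: float,
    baseline: float = 1.0,
    duration_s: float = 900.0,
    n_points: int = 300,
    noise_sd: float = 0.0,
    seed: int = 0,
    floor_fraction: float = 0.2,
) -> pd.DataFrame:
    """Ca-uptake fluorescence time course after ATP addition.

    The Ca-sensitive dye signal decays exponentially from ``baseline``
    toward ``floor_fraction * baseline`` with initial slope ``-rate``
    (fluorescence units / s); ``rate = 0`` gives a flat trace.  Returns a
    table with columns time_s, fluorescence.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    t = np.linspace(0.0, duration_s, n_points)
    amplitude = baseline * (1.0 - floor_fraction)
    if rate <= 0 or amplitude <= 0:
        mu = np.full_like(t, baseline)
    else:
        k = rate / amplitude
        mu = baseline - amplitude * (1.0 - np.exp(-k * t))
    rng = np.random.default_rng(seed)
    y = mu + rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else mu.copy()
    return pd.DataFrame({"time_s": t, "fluorescence": y})
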