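"""Screen-level statistics: interference flagging, hit selection, assay quality.

The primary screen reads every well's donor lifetime in Ch1 plus the
integrated two-channel intensity ratio.  Triage then proceeds in order:

1. **Fluorescent-compound flagging.**  A compound that merely changes FRET
   shifts the lifetime but leaves the Ch2/Ch1 intensity ratio at its
   spectral value; a compound with intrinsic fluorescence distorts the
   ratio.  Wells whose ratio percent-difference from the DMSO mean exceeds
   3 SD (of the DMSO percent-difference distribution, two-sided) are
   flagged and excluded from hit calling.
2. **Hit selection.**  Unflagged compound wells whose mean lifetime departs
   from the DMSO median by more than a 3/5/7 SD threshold are hits, with
   the direction of change (FRET increase = lifetime decrease) recorded.
3. **Counter-screen.**  Hits are retested on a donor-acceptor linker-only
   biosensor; a hit passes only if it leaves the linker lifetime within a
   stricter 3 SD band — rejecting promiscuous fluorophore binders.
4. **Assay quality.**  The robust Z-prime compares tool-compound and DMSO
   control populations via medians and scaled MADs:

       rZ' = 1 - 3 (MAD_tool + MAD_dmso) / |median_tool - median_dmso|,
       MAD = 1.4826 * median(|x_i - median(x)|).

   rZ' > 0.5 (>= 12 SD of control separation for equal-noise Gaussian
   populations) marks an HTS-ready assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import Waveform, fit_decay
from .simulate import SimulatedPlate

__all__ = [
    "WellStat",
    "ControlSummary",
    "ScreenResult",
    "channel_ratio_percent_diff",
    "flag_fluorescent",
    "select_hits",
    "counter_screen",
    "mad",
    "robust_zprime",
    "well_stats_from_plate",
    "run_screen",
]

MIN_DMSO_WELLS = 8


@dataclass(frozen=True)
class WellStat:
    """Per-well screening readout: Ch1 lifetime and two-channel intensities."""

    well: str
    role: str
    mean_tau_ns: float
    intensity_ch1: float
    intensity_ch2: float
    compound_id: str = ""

    @property
    def channel_ratio(self) -> float:
        return self.intensity_ch2 / self.intensity_ch1


@dataclass(frozen=True)
class ControlSummary:
    """Median/MAD summary of one control population (tool compound or DMSO)."""

    label: str
    median: float
    mad: float

    @classmethod
    def from_values(cls, label: str, values) -> "ControlSummary":
        v = np.asarray(values, dtype=float)
        return cls(label=label, median=float(np.median(v)), mad=mad(v))


@dataclass(frozen=True)
class ScreenResult:
    """Tidy per-well triage table plus plate-level summary statistics."""

    table: pd.DataFrame
    summary: dict


def mad(values) -> float:
    """Scaled median absolute deviation: 1.4826 * median(|x - median(x)|).

    The 1.4826 factor makes MAD a consistent estimator of the SD for
    Gaussian data.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mad of an empty sequence")
    if v.size < 2:
        raise ValueError("mad needs at least 2 values")
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


def robust_zprime(tool: ControlSummary, dmso: ControlSummary) -> float:
    """Robust Z-prime of two control populations (may be negative).

    Raises on equal medians (zero dynamic range).  Values above 0.5 indicate
    separation sufficient for high-throughput screening.
    """
    sep = abs(tool.median - dmso.median)
    if sep == 0:
        raise ValueError("zero dynamic range: control medians are equal")
    return 1.0 - 3.0 * (tool.mad + dmso.mad) / sep


def channel_ratio_percent_diff(ratio: float | np.ndarray, dmso_mean_ratio: float):
    """Percent difference of a well's Ch2/Ch1 ratio from the DMSO mean ratio."""
    if dmso_mean_ratio <= 0:
        raise ValueError("DMSO mean ratio must be > 0")
    return 100.0 * (np.asarray(ratio, dtype=float) - dmso_mean_ratio) / dmso_mean_ratio


def _split_roles(wells: list[WellStat]):
    dmso = [w for w in wells if w.role == "dmso"]
    if len(dmso) < MIN_DMSO_WELLS:
        raise ValueError(
            f"need at least {MIN_DMSO_WELLS} DMSO control wells, got {len(dmso)}"
        )
    return dmso


def flag_fluorescent(wells: list[WellStat], n_sd: float = 3.0) -> dict[str, bool]:
    """Two-sided interference flag per non-control well.

    A well is flagged when the percent difference of its channel ratio from
    the DMSO mean exceeds ``n_sd`` times the SD of that percent difference
    over DMSO wells ("more than" — strict inequality).
    """
    dmso = _split_roles(wells)
    mean_ratio = float(np.mean([w.channel_ratio for w in dmso]))
    dmso_pd = channel_ratio_percent_diff(np.array([w.channel_ratio for w in dmso]), mean_ratio)
    sd = float(np.std(dmso_pd, ddof=1))
    if sd == 0:
        raise ValueError("DMSO channel-ratio SD is zero; cannot set a flag threshold")
    out = {}
    for w in wells:
        if w.role != "compound":
            continue
        pdiff = channel_ratio_percent_diff(w.channel_ratio, mean_ratio)
        out[w.well] = bool(abs(pdiff) > n_sd * sd)
    return out


def select_hits(
    wells: list[WellStat],
    threshold_sd: float = 5.0,
    fluorescent_flags: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """SD-threshold hit selection on the Ch1 mean lifetime.

    A compound well is a hit when it is not interference-flagged and its
    lifetime departs from the DMSO median by strictly more than
    ``threshold_sd`` times the DMSO lifetime SD.  Returns a table with
    columns well, compound_id, delta_sd, direction, hit.
    """
    dmso = _split_roles(wells)
    taus = np.array([w.mean_tau_ns for w in dmso])
    center = float(np.median(taus))
    sd = float(np.std(taus, ddof=1))
    if sd == 0:
        raise ValueError("DMSO lifetime SD is zero; cannot set a hit threshold")
    flags = fluorescent_flags or {}
    rows = []
    for w in wells:
        if w.role != "compound":
            continue
        delta_sd = (w.mean_tau_ns - center) / sd
        flagged = flags.get(w.well, False)
        rows.append(
            {
                "well": w.well,
                "compound_id": w.compound_id,
                "delta_sd": delta_sd,
                # lifetime decrease = FRET increase
                "direction": "fret_increase" if delta_sd < 0 else "fret_decrease",
                "hit": bool((not flagged) and abs(delta_sd) > threshold_sd),
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["well", "compound_id", "delta_sd", "direction", "hit"]
    )


def counter_screen(
    hit_compounds: list[str],
    linker_wells: list[WellStat],
    n_sd: float = 3.0,
) -> dict[str, str]:
    """Linker-biosensor counter-screen: 'pass', 'fail' or 'untested' per hit.

    A hit passes when its lifetime shift on the linker-only biosensor stays
    strictly within ``n_sd`` linker-DMSO SDs — i.e. it affects the fusion
    biosensor specifically, not the fluorescent proteins themselves.
    """
    dmso = _split_roles(linker_wells)
    taus = np.array([w.mean_tau_ns for w in dmso])
    center = float(np.median(taus))
    sd = float(np.std(taus, ddof=1))
    by_compound = {w.compound_id: w for w in linker_wells if w.role == "compound" and w.compound_id}
    out = {}
    for cid in hit_compounds:
        w = by_compound.get(cid)
        if w is None:
            out[cid] = "untested"
        else:
            out[cid] = "pass" if abs(w.mean_tau_ns - center) < n_sd * sd else "fail"
    return out


def well_stats_from_plate(
    plate: SimulatedPlate,
    n_components: int = 2,
    fit: bool = True,
) -> list[WellStat]:
    """Fit every well of a simulated plate and assemble WellStat records.

    With ``fit=False`` lifetimes are skipped (NaN) and only intensities are
    computed — enough for ratio-based flagging, and much faster.
    """
    t = plate.irf.grid.times()
    stats = []
    for i, row in enumerate(plate.plate_map.itertuples(index=False)):
        i1 = float(np.trapezoid(plate.ch1[i], t))
        i2 = float(np.trapezoid(plate.ch2[i], t))
        if fit:
            wf = Waveform(time_ns=t, intensity=plate.ch1[i], channel="Ch1", well=row.well)
            tau = fit_decay(wf, plate.irf, n_components=n_components).mean_tau_ns
        else:
            tau = float("nan")
        stats.append(
            WellStat(
                well=row.well,
                role=row.role,
                mean_tau_ns=tau,
                intensity_ch1=i1,
                intensity_ch2=i2,
                compound_id=row.compound_id,
            )
        )
    return stats


def run_screen(
    plate: SimulatedPlate,
    linker_plate: SimulatedPlate | None = None,
    hit_threshold_sd: float = 5.0,
    flag_threshold_sd: float = 3.0,
    counter_threshold_sd: float = 3.0,
    n_components: int = 2,
) -> ScreenResult:
    """Full triage of one plate: fit -> flag -> hits -> counter-screen -> rZ'.

    The plate-level summary reports DMSO lifetime median/SD, channel-ratio
    percent-difference SD, and the robust Z-prime over tool-compound wells
    (None when the plate carries no tool controls).  When ``linker_plate``
    is given, hits are counter-screened against it.
    """
    wells = well_stats_from_plate(plate, n_components=n_components)
    flags = flag_fluorescent(wells, n_sd=flag_threshold_sd)
    hits5 = select_hits(wells, threshold_sd=hit_threshold_sd, fluorescent_flags=flags)
    hits7 = select_hits(wells, threshold_sd=7.0, fluorescent_flags=flags)
    hit7_map = dict(zip(hits7["well"], hits7["hit"]))

    dmso_taus = [w.mean_tau_ns for w in wells if w.role == "dmso"]
    dmso_ratios = [w.channel_ratio for w in wells if w.role == "dmso"]
    mean_ratio = float(np.mean(dmso_ratios))
    dmso_pd = channel_ratio_percent_diff(np.array(dmso_ratios), mean_ratio)

    tool_taus = [w.mean_tau_ns for w in wells if w.role == "tool"]
    rz = None
    if tool_taus:
        rz = robust_zprime(
            ControlSummary.from_values("tool", tool_taus),
            ControlSummary.from_values("dmso", dmso_taus),
        )

    counter = {}
    if linker_plate is not None:
        hit_cids = [cid for cid, h in zip(hits5["compound_id"], hits5["hit"]) if h and cid]
        linker_wells = well_stats_from_plate(linker_plate, n_components=n_components)
        counter = counter_screen(hit_cids, linker_wells, n_sd=counter_threshold_sd)

    by_well = {w.well: w for w in wells}
    rows = []
    for rec in hits5.itertuples(index=False):
        w = by_well[rec.well]
        rows.append(
            {
                "well": rec.well,
                "compound_id": rec.compound_id,
                "mean_tau_ns": w.mean_tau_ns,
                "delta_sd_units": rec.delta_sd,
                "ratio_percent_diff": float(
                    channel_ratio_percent_diff(w.channel_ratio, mean_ratio)
                ),
                "fc_flag": flags.get(rec.well, False),
                "hit5": rec.hit if hit_threshold_sd == 5.0 else None,
                "hit": rec.hit,
                "hit7": bool(hit7_map.get(rec.well, False)),
                "counter_pass": counter.get(rec.compound_id, ""),
            }
        )
    table = pd.DataFrame.from_records(
        rows,
        columns=["well", "compound_id", "mean_tau_ns", "delta_sd_units",
                 "ratio_percent_diff", "fc_flag", "hit5", "hit", "hit7",
                 "counter_pass"],
    )
    summary = {
        "n_wells": len(wells),
        "n_dmso": len(dmso_taus),
        "n_tool": len(tool_taus),
        "dmso_tau_median_ns": float(np.median(dmso_taus)),
        "dmso_tau_sd_ns": float(np.std(dmso_taus, ddof=1)),
        "dmso_ratio_mean": mean_ratio,
        "dmso_ratio_pd_sd": float(np.std(dmso_pd, ddof=1)),
        "n_flagged": int(sum(flags.values())),
        "n_hits": int(table["hit"].sum()) if len(table) else 0,
        "hit_threshold_sd": hit_threshold_sd,
        "plate_rzprime": rz,
    }
    return ScreenResult(table=table, summary=summary)
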