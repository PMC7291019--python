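"""Run the full screen triage on a simulated 384-well plate.

The plate carries DMSO vehicle controls in its outer column pairs, a
tool-compound column (saturating pump inhibitor, -150 ps lifetime shift),
64 library compounds, one planted lifetime-shifting hit and one planted
fluorescent compound.  Triage flags the fluorescent compound from the
two-channel ratio, calls the hit from the 5 SD lifetime threshold, and
scores assay quality with the robust Z-prime.
"""

from flthts import Contaminant, PlantedEffect, PlateLayout, run_screen, simulate_plate

layout = PlateLayout(format=384, n_compounds=64, tool_cols=(2,))
effects = {
    "A5": PlantedEffect("shift", dtau_ns=-0.08),  # ~12 SD FRET-increasing hit
    "B6": PlantedEffect("contaminant", contaminant=Contaminant(0.05, 0.3, 3.5)),
}
plate = simulate_plate(layout, effects=effects, seed=42)
result = run_screen(plate, hit_threshold_sd=5.0)

s = result.summary
print(f"wells: {s['n_wells']} ({s['n_dmso']} DMSO, {s['n_tool']} tool)")
print(f"DMSO lifetime: median {s['dmso_tau_median_ns']:.4f} ns, "
      f"SD {1e3 * s['dmso_tau_sd_ns']:.1f} ps")
print(f"DMSO channel-ratio mean {s['dmso_ratio_mean']:.4f}, "
      f"percent-diff SD {s['dmso_ratio_pd_sd']:.3f}%")
print(f"flagged fluorescent compounds: {s['n_flagged']}")
print(f"hits at {s['hit_threshold_sd']:.0f} SD: {s['n_hits']}")
print(f"robust Z-prime (tool vs DMSO): {s['plate_rzprime']:.3f} "
      f"({'HTS-ready' if s['plate_rzprime'] > 0.5 else 'below the 0.5 gate'})")

t = result.table.set_index("well")
for well in ("A5", "B6"):
    r = t.loc[well]
    print(f"  {well}: delta = {r['delta_sd_units']:+.1f} SD, "
          f"ratio diff = {r['ratio_percent_diff']:+.1f}%, "
          f"fc_flag={bool(r['fc_flag'])}, hit={bool(r['hit'])}")
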