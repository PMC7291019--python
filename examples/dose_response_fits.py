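"""Hill fits: Ca-ATPase pCa50 for two constructs, and a tool-compound EC50.

Generates replicated Ca-ATPase activity-vs-pCa datasets for a pump-only
control (pCa50 6.62) and a pump-inhibitor fusion construct (pCa50 6.38),
refits both with the four-parameter Hill model, and reports the pCa50 shift
with quadrature-propagated SE — the signature of inhibitory regulation of
the pump's apparent calcium affinity.  A lifetime-FRET concentration-
response curve for a subnanomolar inhibitor is then refit for its EC50.
"""

from flthts import hill_fit, pca50_shift, simulate_hill_dataset
from flthts.simulate import (
    ATPASE_CONTROL_TRUTH,
    ATPASE_FUSION_TRUTH,
    PCA_GRID,
    TG_CRC_TRUTH,
    TG_DOSE_GRID_M,
)

ctrl = hill_fit(simulate_hill_dataset(ATPASE_CONTROL_TRUTH, PCA_GRID, seed=1), "pCa")
fus = hill_fit(simulate_hill_dataset(ATPASE_FUSION_TRUTH, PCA_GRID, seed=2), "pCa")

print(f"pump-only control: pCa50 = {ctrl.midpoint:.2f} +/- {ctrl.se_midpoint:.2f} "
      f"(n_H = {ctrl.n_hill:.2f})")
print(f"fusion construct:  pCa50 = {fus.midpoint:.2f} +/- {fus.se_midpoint:.2f} "
      f"(n_H = {fus.n_hill:.2f})")
shift, se = pca50_shift(ctrl, fus)
print(f"pCa50 shift = {shift:.2f} +/- {se:.2f} "
      "(a rightward shift: the fusion needs more Ca2+ for half-max activity)")

crc = hill_fit(simulate_hill_dataset(TG_CRC_TRUTH, TG_DOSE_GRID_M, seed=3),
               x_mode="concentration")
print(f"tool-compound lifetime CRC: EC50 = {1e9 * crc.midpoint:.1f} "
      f"+/- {1e9 * crc.se_midpoint:.1f} nM"
      f" (saturated: {crc.saturated})")
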