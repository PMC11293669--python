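"""Score a set of prediction intervals with PICP, MPIW and NMPIW.

PICP is the fraction of targets falling inside their interval; MPIW is
the mean interval width; NMPIW divides MPIW by the target range R (4 on
the 0-4 pain scale).  The soft variants used inside gradient training
replace the coverage indicator with sigmoid factors of steepness s.
"""

import painpi as pp

batch = pp.IntervalBatch(
    lower=[0.5, 1.2, 0.0, 2.1],
    upper=[2.5, 3.4, 1.0, 3.9],
    target=[1.0, 2.0, 1.5, 3.0],
)

quality = pp.PIQuality.from_batch(batch, nominal=0.85, target_range=4.0)
print(f"PICP  = {quality.picp:.2f}   (3 of 4 targets inside their interval)")
print(f"MPIW  = {quality.mpiw:.2f}   (mean width, pain-scale units)")
print(f"NMPIW = {quality.nmpiw:.3f}  (width relative to the 0-4 range)")
print(f"soft coverage at s=10:  {pp.picp_soft(batch, 10):.4f}")
print(f"soft coverage at s=200: {pp.picp_soft(batch, 200):.4f} "
      "(approaches the hard PICP as s grows)")
print(f"captured-only width:    {pp.mpiw_captured(batch):.2f}")
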