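"""Score a synthetic biopsy phantom and compare against ground truth.

Builds a three-core biopsy phantom (tumor nests, stroma, lymphocyte
clusters, planted mitoses), runs the full biomarker pipeline on the
rasterized mask, and prints the four biomarkers next to the values known
from the constructive geometry.
"""

from tilmorph import PhantomSpec, generate_phantom, panel_from_summary, summarize_slide

spec = PhantomSpec(seed=1)  # defaults: 3 cores, 4 nests, 15% lymphocytes in bulk
mask, mitoses, truth = generate_phantom(spec)

summary = summarize_slide(mask, mitoses)
panel = panel_from_summary(summary)

print(f"phantom: {mask.shape[0]}x{mask.shape[1]} px at {mask.spacing_um} um/px, "
      f"{len(mitoses)} mitoses planted")
print(f"tumor area {summary.tumor_mm2:.3f} mm2, "
      f"lymphocytes {summary.lymphocytes_mm2:.4f} mm2, "
      f"kept mitoses {summary.mitoses_kept}")
print(f"{'biomarker':<8}{'measured':>12}{'ground truth':>14}")
for name in ("ctils", "ltr", "itr", "mtr"):
    got, want = getattr(panel, name), getattr(truth.panel, name)
    print(f"{name:<8}{got:>12.4f}{want:>14.4f}")

# cTILs is the lymphocyte share of the bulk stroma (visual-TIL analogue);
# LTR/ITR relate lymphocytes to tumor globally and by 80-um proximity;
# MTR is kept mitoses per mm2 tumor. Measured values track the continuous
# geometry to within ~1-2% rasterization error.
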