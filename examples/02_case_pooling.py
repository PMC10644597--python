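"""Pool two slides of one case: ratios of sums, not means of ratios.

A case with several biopsy slides is scored as if all cores lay on one
slide: per-slide areas and mitosis counts are summed first and the
biomarker ratios applied to the pooled sums. This differs from averaging
per-slide scores whenever slides have unequal tumor load.
"""

from tilmorph import AreaSummary, ltr, pool_case

slide_a = AreaSummary(lymphocytes_mm2=0.1, tumor_mm2=0.1, slide_id="a")
slide_b = AreaSummary(lymphocytes_mm2=0.0, tumor_mm2=0.3, slide_id="b")

case = pool_case([slide_a, slide_b], case_id="case01")
mean_of_ratios = (ltr(slide_a) + ltr(slide_b)) / 2

print(f"slide a LTR = {ltr(slide_a):.3f}, slide b LTR = {ltr(slide_b):.3f}")
print(f"case LTR (pooled sums)   = {case.ltr:.3f}")
print(f"mean of per-slide ratios = {mean_of_ratios:.3f}  <- NOT what is reported")

# The pooled value 0.1/(0.1+0.4) = 0.200 weights each mm2 of tissue equally;
# the mean of ratios (0.250) would over-weight the small slide.
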