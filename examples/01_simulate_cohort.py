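"""Simulate a small synthetic honey-adulteration cohort and write it to disk.

Builds a 6-honey rice-syrup scenario (pure honey plus 10 % and 50 % v/v
mixtures, three devices, two chromatographic modes), renders every run
as centroid mzML and writes the sample metadata table. The printed
counts are the study arithmetic: honeys x (pure + levels) samples, each
acquired in both modes.
"""

from pathlib import Path
from tempfile import mkdtemp

from honeyscreen import ci_small_design, make_cohort

out = Path(mkdtemp(prefix="honeyscreen_cohort_"))
design = ci_small_design(seed=0)
meta = make_cohort(design, syrup="rice", out_dir=out)

print(f"cohort written to {out}")
print(f"samples: {meta['sample_id'].nunique()}  runs (sample x mode): {len(meta)}")
print(meta[["sample_id", "honey_id", "syrup", "proportion_pct", "device_id", "mode"]].head(6))
print("\nEach row is one LC-MS run; proportion_pct is the syrup volume fraction "
      "the regression model will later estimate.")
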