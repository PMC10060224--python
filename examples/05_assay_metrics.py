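"""Quantifications for the follow-up assays around a screen.

Worked numbers: mitosis-outcome proportions (102/134 normal -> 76%;
83/112 aberrant -> 74%), a 50-fold GFP competition dropout, a foci
threshold fraction, ChIP relative enrichment, caliper tumor volume, and a
two-tailed t-test between groups.
"""

import pandas as pd

from dropscreen import (
    chip_relative_enrichment,
    foci_fraction,
    normalize_competition,
    outcome_proportion,
    tumor_volume,
    two_sample_ttest,
)

normal = outcome_proportion(102, 134)
aberrant = outcome_proportion(83, 112)
print(f"normal mitosis: {normal.n_event}/{normal.n_total} = "
      f"{normal.percent_rounded}% (95% CI {normal.ci_low:.1f}-"
      f"{normal.ci_high:.1f}%)")
print(f"aberrant mitosis: {aberrant.n_event}/{aberrant.n_total} = "
      f"{aberrant.percent_rounded}%")

competition = pd.DataFrame({
    "timepoint": ["d0", "d7", "d14", "d21", "d28"],
    "gfp_percent": [50.0, 30.0, 12.0, 4.0, 1.0],
})
_, summary = normalize_competition(competition)
print(f"\ncompetition assay: d0 {summary.gfp_d0[0]:.0f}% GFP -> final "
      f"{summary.gfp_final[0]:.0f}% = {summary.fold_dropout[0]:.0f}-fold "
      f"dropout (strong depletion of guide-carrying cells)")

cells = [0, 1, 5, 6, 2, 4, 7, 0, 3, 5]
print(f"\ncells with >=4 foci: {foci_fraction(cells, 4):.0f}% "
      f"(threshold fraction over {len(cells)} scored cells)")

enrichment = chip_relative_enrichment(8.0, 2.0, reference_pair=(2.0, 2.0))
print(f"ChIP relative enrichment vs control: {enrichment:.1f}x")

print(f"tumor volume 10 x 8 x 6 mm: {tumor_volume(10, 8, 6):.1f} mm^3")

res = two_sample_ttest([310, 280, 345, 295], [150, 170, 140, 165])
print(f"unpaired t-test: t = {res.t:.2f}, df = {res.df:.0f}, "
      f"p = {res.p:.2e}")
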