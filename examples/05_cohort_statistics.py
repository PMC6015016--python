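"""Cohort statistics: genotype x time ANOVA with Hochberg correction.

Simulates a small wild-type vs transgenic cohort (the full study design is
7 vs 7; 4 vs 4 keeps this example snappy), runs the ROI GCE pipeline for
every subject, and tests each ROI's GCE table for genotype, time and
interaction effects.
"""

from glucocest import PhantomConfig, simulate_cohort
from glucocest.analysis import SubjectData, cohort_gce_table
from glucocest.stats import anova_all_rois

cohort = simulate_cohort(n_wt=4, n_tg=4, config=PhantomConfig(), seed=21)
table = cohort_gce_table(
    [SubjectData.from_sim(s) for s in cohort.subjects],
    rois=("cortex", "hippocampus", "thalamus"),
)

print(table.groupby(["roi", "genotype"])["gce"].mean().round(3).unstack())
print()
for res in anova_all_rois(table, ["cortex", "hippocampus", "thalamus"]):
    for eff in ("genotype", "time", "genotype_x_time"):
        print(f"{res.roi:<12}{eff:<16} F = {res.f[eff]:8.2f}  "
              f"p = {res.p[eff]:.2e}  p_Hochberg = {res.p_adjusted[eff]:.2e}")

print("\nThe transgenic uptake deficit (scaling 0.6) appears as a strong "
      "genotype effect; the saturating uptake curve drives the time effect. "
      "Hochberg adjustment is across the three ROIs per effect.")
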