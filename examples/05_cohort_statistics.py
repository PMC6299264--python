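"""Cohort simulation and the full developmental statistics.

Generates a 99-infant cohort (8 scanned twice) whose metric trajectories
encode the maturational pattern — orientation dispersion rises then plateaus
at 38 weeks post-menstrual age, neurite density dips then rises, mean
diffusivity falls throughout — and runs the complete analysis: partial
Spearman correlations (mixed-effects residualisation for the repeated
scans), the <38 / >=38-week window split, quartile-bounded biphasic
breakpoint regression with AICc model choice, and per-contrast FDR.
"""

import warnings

warnings.filterwarnings("ignore")

from cortimat import SyntheticCohortSpec, simulate_cohort
from cortimat.devstats import StatsConfig, run_cohort_analysis

table = simulate_cohort(SyntheticCohortSpec(seed=10))
print(f"cohort: {len(table)} acquisitions from {table['subject_id'].nunique()} subjects")

config = StatsConfig(regions=tuple(f"r{i:02d}" for i in range(5)))
results = run_cohort_analysis(table, config)

cx = results.trajectories.query("region == 'cortex'")
print("\nwhole-cortex metric-vs-age correlations (covariate-adjusted):")
for _, row in cx.iterrows():
    mark = "*" if row["significant"] else " "
    print(f"  {row['metric']:>9} {row['window']:>6}: rho {row['rho']:+.2f}  "
          f"p {row['p']:.2g} {mark}")

bi = results.biphasic.query("region == 'cortex' and metric == 'ODI'").iloc[0]
print(f"\nODI breakpoint estimate: {bi['breakpoint']:.1f} weeks "
      f"(true 38.0), preferred model: {bi['preferred']}")
print("\nThe starred pattern — dispersion rising only before 38 weeks, neurite")
print("density rising after, diffusivity falling throughout — is the biphasic")
print("cortical maturation signature the pipeline is built to detect.")
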