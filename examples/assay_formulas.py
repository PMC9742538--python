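"""The plate-assay formulas on small example readings.

Autoaggregation: turbidity at the top of a static culture as a percentage
of the vortexed control — a drop over time means cells clump and settle.
Viability: background-corrected WST-8 absorbance relative to uninfected
control cells.  Fold change: cytokine level over the negative control.
"""

from biofilmoct import (
    SedimentationSeries,
    ViabilityReading,
    autoaggregation_percent,
    fold_change,
    viability_percent,
)

# a strongly autoaggregating culture: turbidity collapses within a day
sed = SedimentationSeries(
    time_points_h=[2, 6, 10, 24, 48, 72],
    od_final=[0.48, 0.41, 0.30, 0.12, 0.06, 0.04],
    od_initial=[0.50, 0.50, 0.49, 0.48, 0.47, 0.45],
)
print("sedimentation assay (turbidity % of vortexed control):")
print(sed.to_frame().to_string(index=False, float_format="%.1f"))

# infected macrophages retain ~96% of control metabolic activity
reading = ViabilityReading(a_test=1.32, a_control=1.37, a_background=0.11)
print(f"\ncell viability: {viability_percent(reading):.1f} % of uninfected control")

# IL-6 in infected vs uninfected supernatant
print(f"IL-6 induction: {fold_change(230.0, 5.0):.0f}-fold over negative control")
print(f"single-time-point sanity check: "
      f"{autoaggregation_percent(0.25, 0.50):.1f} % turbidity remaining")
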