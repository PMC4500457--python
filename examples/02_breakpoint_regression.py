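"""Detect the change of regime in the cumulative description curve.

Simulates a survey whose description intensity switches from a slow
quadratic regime to a steep linear one in 2004, then recovers that
change-point by exhaustive two-segment least squares.
"""

from linneangap import (
    AccumulationCurve,
    SimulationConfig,
    fit_breakpoint,
    predict_segmented,
    simulate_counts,
)

config = SimulationConfig(seed=20)
curve = AccumulationCurve.from_counts(simulate_counts(config))
fit = fit_breakpoint(curve)  # quadratic before, linear after

print(f"true change-point year:     {config.changepoint_year}")
print(f"estimated breakpoint year:  {fit.breakpoint_year}")
print(f"cumulative at breakpoint:   {fit.cumulative_at_breakpoint} species")
print(f"post-breakpoint slope:      {fit.post_model[1]:.1f} species/year")
print(f"total SSE of the fit:       {fit.sse_total:.1f}")
print(f"prediction for 2010:        {predict_segmented(fit, 2010):.0f} species "
      f"(observed {curve.cumulative[curve.years.index(2010)]})")

# The breakpoint lands within a year of the simulated regime change, and
# the linear segment's slope recovers the post-change description rate.
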