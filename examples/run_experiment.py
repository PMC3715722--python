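"""Run a small noisy-concentric-adaptor experiment end to end.

Builds an intermixed-layout coherence series plus baseline, simulates
the observer (4 blocks of 70 trials per condition), fits each condition,
and reports tilt aftereffects with bootstrap standard errors.
"""

from remotetae import ObserverParams, build_grid, run_pipeline, summarize

grid = build_grid(
    "exp1",
    {"layouts": ["intermixed"], "coherences": [0.25, 0.5, 0.75, 1.0], "seed": 0},
)
results = run_pipeline(grid, ObserverParams(seed=0), n_boot=500)

print("condition            coherence   TAE (deg)   SE      predicted")
for _, row in results.iterrows():
    print(f"{row.condition_id:<22} {row.coherence:5.2f}   {row.tae:+7.3f}  "
          f"{row.tae_se:5.3f}    {row.predicted_tae:+.3f}")

report = summarize(results)
print(f"\nTAE grows with structure coherence "
      f"(slope {report['coherence_slope']:+.2f} deg per unit coherence); "
      "fully coherent circular structure yields the ~2 deg remote aftereffect.")
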