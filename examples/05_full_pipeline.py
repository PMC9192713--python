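"""Run the complete pipeline: synthesize, measure, fit, correlate.

Generates a cohort, measures sensitivity with staircases, measures wedge
areas on per-observer synthetic cortices, runs a pRF simulate-and-refit
diagnostic on one observer, and reports the asymmetry statistics with
recovery diagnostics against the planted ground truth.  Takes a couple of
minutes at the default resolutions.
"""

import json

import cortmag as cm

config = cm.RunConfig(seed=1)
report = cm.run_pipeline(config)

print("group indices (measured vs planted):")
for k, v in report["group_indices"].items():
    print(f"  {k}: {v:6.1f}  (planted {report['planted_group_indices'][k]:6.1f})")
print(f"pooled rho: {report['pooled_rho']:.3f} "
      f"(planted {report['planted_pooled_rho']:.3f})")
print(f"null x0.95: across-observers {report['null_across_observers_x95']:.3f}, "
      f"across-locations {report['null_across_locations_x95']:.3f}")
print(f"pRF recovery: {json.dumps(report['prf_recovery'][0], indent=2)}")
print("Measured indices and pooled rho should track the planted values; "
      "the pooled rho should exceed both null cut-offs.")
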