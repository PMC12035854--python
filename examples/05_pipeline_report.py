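"""Run the full pipeline: synthesize events, fit EM, score the fit.

Writes events.tsv, model.json, events_classified.tsv and report.json
into ./scratch/pipeline_demo and prints the headline numbers, including
the L1 discrepancy between the fitted force density and a kernel
density estimate of the data.
"""

import json

from fibrinpull import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1, out_dir="scratch/pipeline_demo", n_events=3000)
report = run_pipeline(config)

print(json.dumps(report["em"], indent=1))
print(
    f"\ncombined L1(model, KDE) = {report['l1']['combined']:.3f} "
    "(0 = identical densities, 2 = disjoint)"
)
print(
    "per-type L1:",
    [round(v, 3) for v in report["l1"]["per_type"]],
)
print(
    "\nA small combined L1 says the five-component Gamma mixture "
    "reproduces the overall unfolding-force distribution it was fit to."
)
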