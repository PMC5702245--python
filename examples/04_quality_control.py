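"""Model quality control.

Runs the three curation tests on the bundled network: every reaction must be
able to carry flux with the boundary open, no metabolite may be a dead end,
and a fully closed system must not produce ATP (or PMF/NADH/NADPH) from
nothing.  A charge/element balance sweep completes the report.
"""

from mitoflux import build_reduced_model, run_qc

model = build_reduced_model(qc=False)
report = run_qc(model)
print(report.to_json())
print(
    "\n'passed: true' means the network is free of blocked reactions, dead "
    "ends,\nbalance errors and energy-generating cycles - the failure modes "
    "that make\nlarger automatically assembled models produce spurious ATP."
)
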