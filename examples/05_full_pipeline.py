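"""One-call pipeline: simulate, code, describe, fit, render.

Writes the full report bundle (tables, JSON, figure) to ./pipeline_output
and prints the headline numbers.  Equivalent shell command:

    twinace run --seed 1 --out pipeline_output
"""

from twinace import PipelineConfig, SimulationConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(
    simulation=SimulationConfig(),
    model=1,
    seed=1,
    out_dir="pipeline_output",
))

print(f"\nprevalence: {bundle['descriptives']['total']['prevalence_pct']:.2f}%")
print(f"chi2 sex difference: {bundle['sex_difference']['chi2']:.1f}, "
      f"OR = {bundle['sex_difference']['odds_ratio']:.2f}")
for label, corr in bundle["twin_correlations"].items():
    print(f"{label} tetrachoric r = {corr['r']:.2f}")
ace = bundle["variance_components"]["ACE"]
print(f"ACE: a2 = {ace['a2']:.2f}, c2 = {ace['c2']:.2f}, e2 = {ace['e2']:.2f}")
print("full bundle written to pipeline_output/ (tables, JSON, figure)")
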