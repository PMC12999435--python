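"""Run the whole pipeline on a synthetic cohort and list its artifacts.

Equivalent to `immunebalance run-all --seed 7 --out pipeline_out` with a
simulation config; every artifact is stamped with the config hash and seed.
"""

from pathlib import Path

from immunebalance import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    simulation=SimulationConfig(seed=7).scale_effects(2.0),
    seed=7,
    outdir="pipeline_out",
)
report = run_pipeline(cfg)

print(Path(cfg.outdir, "summary.txt").read_text())
print("artifacts:")
for p in sorted(Path(cfg.outdir).iterdir()):
    print(" ", p.name)
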