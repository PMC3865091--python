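"""Run the whole pipeline end to end and list what it writes.

Equivalent to `comodnet all --seed 42 --out comodnet_out` on the command
line: simulation, preprocessing, differential expression, coexpression for
both omics, cross-omic integration and the integrative network, with a run
manifest for reproducibility.
"""

from comodnet import PipelineConfig, run_all

cfg = PipelineConfig(seed=42)
manifest = run_all(cfg, "comodnet_out")
print(f"pipeline version {manifest.version}, seed {manifest.seed}")
print(f"config hash {manifest.config_hash[:12]}...")
print("outputs:")
for name in manifest.outputs:
    print(f"  comodnet_out/{name}")
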