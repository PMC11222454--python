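"""End-to-end run with the miRNA prioritisation cascade.

Runs the whole pipeline on a study-shaped synthetic dataset (5 time-points x
3 replicates + controls, reduced bootstrap count for speed), then prints the
per-stage shortlist counts and the annotated miRNA-mRNA interactions.
"""

import tempfile

from temponet.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    output_dir=tempfile.mkdtemp(prefix="temponet_example_"),
    B=100,
    rng_seed=11,
)
result = run_pipeline(config)

print(f"time-points modelled: {list(result.networks)}")
print(f"retained edges per time-point: "
      f"{ {tp: len(n.retained_arcs()) for tp, n in result.networks.items()} }")
print(f"beta indices: { {tp: round(b, 2) for tp, b in result.beta_indices.items()} }")
print("\nshortlist cascade (DE miRNAs -> has targets -> has human orthologue "
      "-> targets at >=2 time-points -> seed conserved):")
for stage, count in result.cascade_counts.items():
    print(f"  {stage:<28} {count}")
print(f"\ndistinct miRNA->mRNA interactions (MTIs): {len(result.mti)}")
if result.annotated is not None and len(result.annotated):
    conf = result.annotated["confidence"].value_counts().to_dict()
    print(f"MTI confidence classes after resource annotation: {conf}")
print(f"\nall stage outputs persisted under {config.output_dir}")
print("At the real study's sample size (15), single networks are unstable; "
      "the bootstrap strengths and the cascade make the shortlist conservative.")
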