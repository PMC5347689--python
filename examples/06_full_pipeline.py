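"""Full pipeline run from the demo config: simulate both platforms,
normalize, filter, train, score, classify, validate, and compute power.

Equivalent shell command:
    e2fscore run-all --config examples/demo_config.yaml --outdir scratch/demo
"""

import logging
from pathlib import Path

from e2fscore import PipelineConfig, run_pipeline

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

config = PipelineConfig.from_file(Path(__file__).parent / "demo_config.yaml")
manifest = run_pipeline(config, "scratch/demo_pipeline")

print(f"\nconfig hash: {manifest['config_hash']}, seed {manifest['seed']}")
print(f"{len(manifest['files'])} artifacts:")
for name in sorted(manifest["files"]):
    print(f"  {name}")
# Rerunning with the same config and seed reproduces every file
# byte-for-byte; the manifest records a sha256 per artifact.
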