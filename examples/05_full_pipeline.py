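"""Run the whole analysis pipeline programmatically.

Equivalent to `spnmorph all --config config.yaml`: generate a cohort,
standardise, slice + repair, morphometry, spine statistics and a passive
simulation, with a deterministic JSON summary.
"""

import json
import tempfile

from spnmorph.pipeline import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = PipelineConfig(species="mouse", out_dir=tmp, n_cells=4, seed=3)
    summary = run_pipeline(config)
    print(json.dumps({k: v for k, v in summary.items() if k != "out_dir"},
                     indent=2, sort_keys=True, default=str))
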