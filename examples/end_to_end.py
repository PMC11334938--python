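"""Full pipeline: simulate a study to disk, run every stage, read the report.

Equivalent to:  sphingolink simulate --outdir ds && sphingolink run ds --outdir out
"""

import json
import tempfile
from pathlib import Path

from sphingolink import SimConfig, run_pipeline, write_dataset

with tempfile.TemporaryDirectory() as tmp:
    ds = Path(tmp) / "dataset"
    cfg = SimConfig(seed=6, n_mags=40, n_producer_mags=5, n_lipids=21,
                    scaffolds_per_mag=(12, 15))
    write_dataset(cfg, ds)
    print("dataset files:", sorted(p.name for p in ds.iterdir()))

    report = run_pipeline(ds, outdir=Path(tmp) / "out")
    print(json.dumps({k: report[k] for k in
                      ("network", "screen", "coabundance", "truth")},
                     indent=1, default=float))
# The report aggregates every stage: subnetwork counts, Spt-like
# scaffold/MAG counts, gated/naive edge counts with the reduction ratio,
# and precision/recall against the planted truth.
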