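"""Run the complete analysis pipeline and write a report bundle.

Equivalent to `spiderpref run --out report_dir`: simulate (or load) a
cohort, validate the design, summarize, correlate, fit splines, cluster,
and write every artifact as CSV/JSON with a provenance block.
"""

import tempfile
from pathlib import Path

import spiderpref as sp

config = sp.PipelineConfig(generator=sp.reference_config(), seed=1)
out = Path(tempfile.mkdtemp()) / "report"
bundle = sp.run_pipeline(config, out_dir=out)

print(f"bundle written to {out}")
print(f"provenance: config {bundle.provenance['config_hash']}, "
      f"seed {bundle.provenance['seed']}, "
      f"version {bundle.provenance['version']}")
print(f"spline fits: {len(bundle.spline_fits)} "
      "(6 preference responses + 3 incoherency responses)")
print(f"clusterings: {len(bundle.clusterings)} criteria")
print("files:", ", ".join(sorted(p.name for p in out.iterdir())))
print("\nRe-running with the same config and seed reproduces every file "
      "byte for byte.")
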