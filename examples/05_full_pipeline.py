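"""Run the whole pipeline from one configuration and render the report.

genome build -> repeat scan -> conformations -> read simulation ->
classification -> support table -> multipartite model -> homology/MTPT ->
Markdown report.  All outputs are plain text and byte-reproducible for a
fixed seed.
"""

import logging
from pathlib import Path

import mitoforms as mf

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

outdir = Path("scratch/pipeline_demo")
results = mf.run_pipeline(None, outdir)  # None -> package default configuration

print(f"\noutputs written to {outdir}/:")
for f in sorted(outdir.iterdir()):
    print(f"  {f.name}")

print("\n--- report.md ---\n")
print((outdir / "report.md").read_text())
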