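"""End-to-end pipeline run from a config dict.

Structure -> {normal modes, CG-MD + essential dynamics} -> normalized
B-factor table, overlap table, per-method and composite DCCMs, manifest.
The same run is available from the shell:  enmdyn pipeline --config run.yaml
"""
from pathlib import Path

from enmdyn import RunConfig, run_pipeline

outdir = Path("scratch/pipeline_demo")
config = RunConfig(
    outdir=outdir,
    synthetic={"n_core": 60, "n_insert": 30, "seed": 1},
    cmd={"n_steps": 50_000, "save_every": 10, "seed": 11},
)
paths = run_pipeline(config)

print(f"report bundle in {outdir}/")
for key in ("bfactors", "overlaps", "dccm_nma", "dccm_eda",
            "dccm_composite", "manifest"):
    print(f"  {paths[key].name}")

table = paths["overlap_table"].table
full = table[table["scope"] == "full"]
print("\nfull-protein NMA-vs-CEDA overlaps (index-paired):")
print(full[["mode", "overlap"]].to_string(index=False))
print("\n-> every number in the bundle is reproducible bit-for-bit from "
      "this config and seed (see manifest.json).")
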