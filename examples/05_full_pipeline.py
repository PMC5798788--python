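"""Run the whole pipeline (traits -> Mantel -> GLMM -> GLMs) from one
configuration and inspect the run directory.

The same thing is available from the shell:

    phylogerm simulate --seed 1 --out data/
    phylogerm run-all --config config.yaml --out run/
"""

import tempfile
from pathlib import Path

import phylogerm as pg
from phylogerm import pipeline, simulate, traits

base = Path(tempfile.mkdtemp(prefix="phylogerm_"))
records, truth = pg.simulate_germination(pg.SimulationConfig(seed=1))
traits.write_plates_csv(records, base / "plates.csv")
(base / "species.nwk").write_text(truth.tree_newick + "\n")
simulate.simulate_climate(truth.populations, seed=2).to_csv(
    base / "climate.csv", index=False
)

config = {
    "seed": 1,
    "inputs": {
        "plates": str(base / "plates.csv"),
        "tree": str(base / "species.nwk"),
        "climate_monthly": str(base / "climate.csv"),
    },
    "mantel": {"perms": 2000},
    # desk-scale MCMC so the example finishes in a few minutes; remove these
    # overrides for study-scale runs
    "pglmm": {"chains": 2, "adapt": 500, "burnin": 500, "samples_per_chain": 2000, "thin": 1},
}
run_dir = pipeline.run_pipeline(config, base / "run")
print((run_dir / "report.txt").read_text())
print(f"stage outputs, manifest.json and report.txt are in {run_dir}")
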