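"""Full between-condition comparison on a synthetic heat-shock emulation.

Runs the bundled pipeline end to end on a reduced synthetic configuration
and prints the comparison report: weighted-topology shifts, the module
decomposition of each condition, and the nonparametric tests.
"""

import tempfile
from pathlib import Path

import stressnet as sn
from stressnet.pipeline import RunConfig

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(
        synthetic_network={
            "n_modules": 6, "module_size": 60, "overlap_nodes_per_pair": 4,
            "p_intra": 0.9, "p_inter": 0.01, "hub_boost": 6,
        },
        synthetic_stress={"up_modules": [5], "down_modules": [0, 1]},
        outdir=str(Path(tmp) / "run"),
        seed=1,
    )
    report = sn.run(config)
    print((Path(tmp) / "run" / "comparison.txt").read_text())

print("Reading the report: the weighted diameter ratio above 1 means the stressed")
print("interactome became a 'larger world'; fewer hubs and lower effective degrees")
print("mean connection weight moved off the hub-like proteins; the Wilcoxon lines")
print("give two-sided paired tests over edges/nodes, the Mann-Whitney line an")
print("unpaired test over the modules of the two decompositions.")
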