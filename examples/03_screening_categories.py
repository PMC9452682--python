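"""(S_n, O_m) response categorization and the triangle map.

Every perturbation (a node, one of its outgoing links, or a pair) is
classified by two axes: selective control S1-S4 (is the node effective, only
the node, only a link, or neither -- efficacy > 0.8) and optimal control
O1-O3 (toxicity test max f - max g > 0.5, else potency test f(x) - g(x) >
0.5 at some dose, else no window).  (S1-S3, O1-O2) are desirable (D)
responses.  The full screen over the six designated target nodes has 480
perturbations; here a two-node subset is screened at reduced resolution to
stay interactive.
"""

from collections import Counter

from netwin import (
    CONTROL_PROFILE,
    AlterationProfile,
    SimulationConfig,
    alterations_to_status,
    enumerate_perturbations,
    triangle_map,
)
from netwin.fixtures import P53_TARGET_NODES, load_p53, load_p53_gene_map

net = load_p53()
gene_map = load_p53_gene_map()

full = enumerate_perturbations(net, P53_TARGET_NODES)
print(f"full screening set over {P53_TARGET_NODES}: {len(full)} perturbations")

config = SimulationConfig(
    input_clamp={"DNA_damage": 1}, seed=0,
    enumeration_cap=10, n_samples=512, transient_steps=60, steady_steps=60,
)
cancer = alterations_to_status(
    AlterationProfile("case", "cell_line", frozenset({"BCL2_inact"})), gene_map
)
tm = triangle_map(net, cancer, CONTROL_PROFILE, ["AKT", "BCL2"], config)
frame = tm.to_frame()
census = Counter(f"({r.S},{r.O})" for r in frame.itertuples() if r.S != "NA")
print(f"scaled-down screen (AKT, BCL2): {sum(census.values())} classified, "
      f"{len(tm.na)} NA cells (same-source link pairs, node with own link)")
for cat, n in sorted(census.items()):
    print(f"  {cat}: {n}")
desirable = frame[(frame.S != "NA") & frame.desirable]
print(f"desirable responses: {len(desirable)}, e.g. {desirable.perturbation.iloc[0]}")
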