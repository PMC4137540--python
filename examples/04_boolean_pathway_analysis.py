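"""Attractors and safety properties of an asynchronous Boolean pathway.

Loads the illustrative 10-node signal-transduction network (a ligand ->
receptor -> RAS -> ERK proliferation arm gated by p21, and a P53-MDM2
negative feedback loop), finds its attractors — the P53-MDM2 loop sustains
an oscillation — and model-checks a safety property: proliferation cannot
switch on while the ligand is absent.
"""

from crossscale.boolnet import (
    check_safety, find_attractors, make_pathway_network, reachable,
)

net = make_pathway_network()
print(f"network: {net.n} nodes: {', '.join(net.nodes)}")

attractors = find_attractors(net)
print(f"\nattractors ({len(attractors)}):")
for a in attractors:
    states = sorted("".join("1" if v else "0" for v in s) for s in a.states)
    preview = states if len(states) <= 4 else states[:4] + ["..."]
    print(f"  {a.kind}: {len(a.states)} states  {preview}")
# The cyclic attractors are the P53-MDM2 oscillation (with and without
# ligand-driven proliferative signaling).

i_lig = net.nodes.index("ligand")
i_prolif = net.nodes.index("proliferation")
off = tuple(False for _ in net.nodes)

safe, _ = check_safety(net, [off], lambda s: not s[i_prolif])
print(f"\nAG !proliferation from the all-off state (no ligand): {safe}")

on = tuple(n == "ligand" for n in net.nodes)
hit, path = reachable(net, [on], lambda s: s[i_prolif])
print(f"EF proliferation once ligand is present: {hit} "
      f"(shortest witness: {len(path) - 1} updates)")
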