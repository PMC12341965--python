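"""Assemble a default logic model from a signed network and list its
stable states.

Each node's rule OR-joins its activators, OR-joins its inhibitors, and
links the two groups with AND-NOT (activation required and inhibition
absent).  The stable states (fixed points of x = f(x)) are the only
attractors the pipeline uses.
"""

import synlogic as sl

network = sl.build_network([
    sl.SignedInteraction("GF", "RAS", 1),     # growth signal activates RAS
    sl.SignedInteraction("RAS", "ERK", 1),
    sl.SignedInteraction("ERK", "GF", 1),     # feedback closes the loop
    sl.SignedInteraction("PTEN", "ERK", -1),  # phosphatase inhibits ERK
    sl.SignedInteraction("ERK", "PTEN", -1),
])

model = sl.assemble_default_model(network)
print("Logic equations:")
for eq in model.equations:
    print("  ", eq.to_text())

attractors = sl.fixed_points(model)
print(f"\n{attractors.n} stable state(s) over nodes {attractors.nodes}:")
for state in attractors.fixed_points:
    print("  ", dict(zip(attractors.nodes, state)))
print("\nEach row satisfies f(x) = x: no node would change state, so the")
print("model rests there regardless of the update scheme.")
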