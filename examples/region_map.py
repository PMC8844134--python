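"""Map functional-response shape over attack-learning parameter space.

Sweeps a 21x21 grid of initial attack rate a0 versus learning rate la (am =
1, handling fixed at 0.1) and prints a coarse region map: type III fills the
low-a0/high-la corner, type II the rest.  The full study design uses a
1001x1001 grid; pass larger GridSpec counts to refine.
"""

from funcresp import GridSpec, ShapeType, sweep_attack_learning

res = sweep_attack_learning(
    GridSpec("a0", 0.01, 1.0, 21),
    GridSpec("la", 0.0, 1.0, 21),
)

glyph = {
    ShapeType.TYPE_I: "I",
    ShapeType.NEAR_TYPE_I: "i",
    ShapeType.TYPE_II: ".",
    ShapeType.NEAR_TYPE_II: "+",
    ShapeType.TYPE_III: "#",
}

print("rows: la from 1.0 (top) to 0.0; cols: a0 from 0.01 to 1.0")
for j in range(len(res.y_values) - 1, -1, -1):
    row = "".join(glyph[s] for s in res.shape[j])
    print(f"la={res.y_values[j]:4.2f}  {row}")
print("\ncell counts:", {k: v for k, v in res.shape_counts().items() if v})
print(
    "\n'#' marks sigmoid (type III) responses: they need a low initial"
    "\nattack rate (room to learn) and a nonzero learning rate."
)
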