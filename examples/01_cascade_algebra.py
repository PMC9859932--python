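"""Cascades, the tropical semiring, and gene elimination by quotient.

Builds the possessed-cascade set of a toy cell from a dependency oracle,
shows the per-cascade tropical operations, and demonstrates that deleting
genes through the semiring quotient gives exactly the induced subgraph —
the formal licence for ignoring off-panel genes.
"""

from eigencascade import (
    EPSILON,
    Cascade,
    RestrictionSpec,
    cascades_from_dependency,
    restrict_induced,
    restrict_quotient,
    to_undirected,
    tropical_add,
    tropical_mul,
    z_map,
)

# A three-gene cell: a depends on b, h depends on a.
deps = {("a", "b"), ("h", "a")}
cell = cascades_from_dependency(lambda x, y: (x, y) in deps, {"a", "b", "h"})
print("possessed cascades:", sorted(map(repr, cell)))
# Singletons are vertices, pairs are edges: |C| = |V| + |E|.
print(f"|C| = {len(cell)} = |V| {len(cell.vertexes())} + |E| {len(cell.edges())}")

# Each cascade carries a semiring on its members plus the environment ε.
ctx = Cascade.pair("a", "b")
print("\ntropical operations on", ctx)
print("  a ⊕ b =", tropical_add("a", "b", ctx), " (the dependent gene absorbs)")
print("  b ⊙ b =", tropical_mul("b", "b", ctx), " (non-neutral elements collapse)")
print("  z(ε)  =", z_map(EPSILON, ctx), " (the homomorphism sends ε to ∞)")

# Restrict the universe to F = {a, b}: the quotient drops h-dependent
# cascades and strips h from the rest; the result is the induced subgraph.
spec = RestrictionSpec(cell.universe, {"a", "b"})
quotient = restrict_quotient(cell, spec)
induced = restrict_induced(cell, spec)
print("\nquotient restriction:", sorted(map(repr, quotient)))
print("induced restriction: ", sorted(map(repr, induced)))
print("identical:", quotient.cascades == induced.cascades)

print("\nundirected form:", sorted(map(repr, to_undirected(cell))))
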