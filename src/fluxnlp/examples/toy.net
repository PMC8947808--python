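# Toy network: substrate A is converted to product B through three routes
# with distinct carbon rearrangements, one of them reversible and one
# passing through a cleavage/condensation pair.  Each route deposits
# substrate carbon 1 at a different product position (B1, B3, B2), so a
# positionally labeled tracer resolves the route split.  With the uptake
# flux v0 known exactly there are three independent fluxes and six
# intracellular pool sizes; the flux and pool information lives in the
# labeling transient after the feed switch.
v0: Aext (abc) -> A (abc)
v1: A (abc) -> B (abc)
v2: A (abc) -> C (bca)
v3: C (abc) -> B (abc)
v4: A (abc) <-> D (cba)
v5: D (abc) -> E (ab) + F (c)
v6: E (ab) + F (c) -> B (acb)
v7: B (abc) -> Bsink (abc)
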