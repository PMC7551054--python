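"""b/y fragment ladders of a cyclic depsipeptide from its two ring openings.

Prints the theoretical singly protonated b/y series of the mono-brominated
Thr-Xle-Asn-Asn-Xle compound for both ring-opening sites, and verifies the
complementary-pair mass conservation b_k + y_{n-k} = [M+H]+ + proton.
"""
from bromonet import (
    DEFAULT_OPENINGS,
    fragment_ladders,
    load_compound_library,
    precursor_mz,
)

model = next(
    c.model for c in load_compound_library() if c.name == "bromoalterochromide D"
)
mh = precursor_mz(model)
print(f"{model.label}: {model.sequence()}, [M+H]+ = {mh:.4f}")

for rule in DEFAULT_OPENINGS:
    ions = fragment_ladders(model, rule)
    b = {f.index: f.mz for f in ions if f.series == "b"}
    y = {f.index: f.mz for f in ions if f.series == "y"}
    print(f"\nopening at {rule.site}:")
    print("  k    b_k         y_k")
    for k in range(1, model.n):
        print(f"  {k}  {b[k]:9.4f}  {y[k]:9.4f}")
    worst = max(abs(b[k] + y[model.n - k] - mh - 1.00728) for k in range(1, model.n))
    print(f"  max |b_k + y_(n-k) - [M+H]+ - proton| = {worst:.2e} Da")
# The y1/y2 values (132.1019, 246.1448 for the ester opening) are the
# C-terminal Xle and Asn-Xle acids; b ions carry the brominated acyl chain.
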