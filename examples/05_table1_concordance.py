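"""Directional concordance of the packaged protein/mRNA fold-change table.

The fixture transcribes the published table of 42 hypothalamic proteins
regulated by dopamine agonists in goldfish, with their matched ESTs and
signed fold changes. A pair counts toward a treatment only when both
layers carry a fold change there; it agrees when the signs match.
"""

import json

from concord import load_table1_fixture, summarize_table1
from concord.concordance import agreement_null_test, direction_agreement

table = load_table1_fixture()
print(f"{len(table)} rows, {table.protein_acc.nunique()} distinct proteins, "
      f"{table[table.mrna_acc != ''].protein_acc.nunique()} with matched mRNA")

for t in ("SKF", "LY"):
    a = direction_agreement(table, t)
    print(f"{t}: {a.n_agree}/{a.n_pairs} pairs share direction "
          f"({100 * a.fraction:.0f}%)")

null = agreement_null_test(table, "LY", n_perm=20000, seed=0)
print(f"LY agreement vs independent-sign null: exact binomial "
      f"p = {null['p_binomial']:.3f} (permutation {null['p_perm']:.3f})")

print("\nfull summary (note the SKF denominator caveat):")
print(json.dumps(summarize_table1(table), indent=2))
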