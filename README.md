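# rxnhasse

Extraction and scoring of enzymatic reaction templates via extended Hasse
diagrams of imaginary transition structures.

## The problem

Predicting whether an enzyme will accept a non-native substrate is a core
task in biocatalysis and enzymatic cascade design. Classic approaches
either apply a reaction rule at a fixed, user-chosen specificity (a fixed
number of bonds around the reaction center) or rank candidates by
fingerprint similarity to known substrates. Both ignore *substrate
promiscuity*: a specialist enzyme demands much closer analogues than a
generalist, so a single similarity threshold or rule radius cannot serve
both.

`rxnhasse` is for practitioners who have a handful of reactions known to
be catalyzed by one enzyme (e.g. from BRENDA-style records) and want
(a) reaction rules at the specificity the data itself supports, and
(b) a score for new substrates or reactions that accounts for the
enzyme's estimated promiscuity, the diversity of its known substrates,
regiochemistry, and missing cosubstrates.

## The method

Each balanced, atom-mapped reaction is superposed into its **imaginary
transition structure (ITS)**: one graph node per mapped atom, one edge per
bond present on either side, each edge carrying a reactant-side and a
product-side bond order. The **reaction center** is the subgraph of
changed atoms, changed bonds, and unchanged bonds between changed atoms.

Starting from the center, templates grow by **conserved-substructure
expansion**: atoms with unspecified neighbors are shortlisted, and the
largest subset whose full-neighborhood expansion yields the identical
enlarged template in *every* ITS is expanded (ties favor fewer
hydrogens; rings complete in one step). When no common expansion exists,
every shortlisted atom is expanded per ITS and the tree branches. The
result is an **extended Hasse diagram**: a rooted tree ordered by
subgraph containment, from the center down to the full input ITSs (the
leaves). The deepest template above the first branch point is the most
specific rule that covers all known reactions.

Queries are scored by descending the tree to the deepest matching
template and combining four components:

    score = S_S − S_P + S_M − 0.1 · S_L

* `S_S` — max Tanimoto similarity (Morgan, radius 2, 2048 bits) between
  query and the known substrates *in the matched branch*;
* `S_P` — mean pairwise similarity of all substrates in the tree, capped
  at 0.8 (1 − S_P estimates promiscuity);
* `S_M` — mean similarity of the query to *all* known substrates;
* `S_L` — tree edges from the matched template to its nearest leaf,
  capped at 5, minus 1.

Substrate-only queries additionally enumerate every reaction site
(regiochemistry), derive the products by applying the per-side bond
orders of the template, and propose cosubstrates from the tree's leaves
for multireactant transformations.

## Worked example

The lyase EC 4.1.3.42 splits a C–C bond next to a hydroxyl group in three
known substrates (4-hydroxy-2-oxoglutarate, 4-hydroxy-2-oxobutanoate,
oxaloacetate), always releasing pyruvate:

```python
import rxnhasse as rh
from rxnhasse import families

d = rh.build_diagram(families.ec_4_1_3_42_reactions())
print(d.text_tree())
```

```
[0] template: 4 atoms
  [1] template: 7 atoms
    [2] template: 9 atoms
      [3] template: 11 atoms
        [4] leaf: 13 atoms  substrates: O=C([O-])C(=O)CCO
        [5] template: 13 atoms
          [6] leaf: 15 atoms  substrates: O=C([O-])C(=O)CC(O)C(=O)[O-]
        [7] leaf: 12 atoms  substrates: O=C(O)CC(=O)C(=O)[O-]
```

A linear chain of four templates grows from the reaction center (node 0)
to the most specific common template (node 3, the full pyruvate moiety
plus the cleaved C–C bond), then splits into three branches — two ending
directly in leaves. A radius-1 extraction on the same reactions would
instead yield three mutually incompatible templates.

Scoring a substrate with unknown products proposes the transformation:

```python
res = rh.score_query_substrate(d, ["OC(=O)CC(=O)C(=O)[O-]"])  # oxaloacetate
print(round(res[0].score, 3), res[0].products)
```

```
1.27 ['O=C=O', 'CC(=O)C(=O)[O-]']
```

The score 1.27 decomposes as `S_S = 1.0`, `S_P = 0.386`, `S_M = 0.655`,
`S_L = 0` — a known substrate of a moderately promiscuous enzyme scores
far above the 0.5 activity threshold, and the proposed products are
carbon dioxide and pyruvate.

The same workflows are available from the shell:

```bash
rxnhasse make-fixtures --family lyase --out lyase.rsmi
rxnhasse train lyase.rsmi --out tree.json
rxnhasse predict --tree tree.json --query "OC(=O)CC(=O)C(=O)[O-]" --mode substrate
```

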