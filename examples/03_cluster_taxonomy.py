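"""The three cluster-taxonomy systems on a mixed cluster.

A cluster holding 97 Escherichia coli and 3 Shigella flexneri operon
sequences: the lowest common ancestor (taxLCA) can only claim the
shared family, while the strict-majority system (taxMaj) keeps the
species carried by 97 % of the members.
"""

from rrndb import taxonomy as tx

ecoli = tx.parse_lineage(
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;"
    "o__Enterobacterales;f__Enterobacteriaceae;g__Escherichia;"
    "s__Escherichia coli")
shigella = tx.parse_lineage(
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;"
    "o__Enterobacterales;f__Enterobacteriaceae;g__Shigella;"
    "s__Shigella flexneri")

cluster = [ecoli] * 97 + [shigella] * 3
print("taxLCA:", tx.format_lineage(tx.tax_lca(cluster)))
print("taxMaj:", tx.format_lineage(tx.tax_maj(cluster)))
print()
print("taxLCA stops at f__Enterobacteriaceae because the two genera "
      "disagree below the family; taxMaj returns s__Escherichia coli "
      "because a strict majority (97/100) shares that full lineage.")
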