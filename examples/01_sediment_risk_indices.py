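"""Sediment risk screening with SQG-Q indices.

Loads the bundled five-site estuary chemistry table, contrasts each
analyte to its marine probable effects level (PEL), and prints the
class and total quotients with the impact classification.
"""

from sedtriad import datasets
from sedtriad.sqgq import sqgq_table

chem = datasets.load_sediment_chemistry()
guidelines = datasets.load_guidelines()

table = sqgq_table(chem, guidelines)
print(table.round(2).to_string(index=False))
print()
print("A quotient of 1 means the concentration sits exactly at the PEL;")
print("totals below 0.1 classify a sediment as unimpacted, 0.1-1 as")
print("moderately impacted.  The reference site R is clean (total 0.02)")
print("while both estuary arms are moderately impacted, driven by metals.")
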