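"""The Integrated Biomarker Response on the bundled field-biomarker panel.

Nine oxidative-stress biomarkers from clam, sole and cuttlefish across
three areas are standardized (pooled-total), direction-adjusted (the
GSH/GSSG ratio falls under stress), turned into partial scores and
star-plot areas, and summed into one IBR per area.
"""

from sedtriad import datasets
from sedtriad.ibr import global_ibr

panel = datasets.load_biomarker_panel()
result = global_ibr(panel)

print("partial scores S (rows = biomarkers in star order):")
print(result.scores.round(3).to_string())
print("\nglobal IBR per area:")
print(result.ibr.round(2).to_string())
print("\nspecies contributions (partition of the global star):")
print(result.species_scores.round(2).to_string())
print()
print("The reference scenario scores essentially zero (IBR 0.01) while both")
print("estuary arms show clear integrated stress; clams and fish peak in the")
print("southern area, cuttlefish in the northern one.")
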