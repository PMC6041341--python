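"""Summarise family-size change with the F-index.

F = n / (n + x̄) compares a species' gene count n in one family with the
family's mean size x̄ across all species: 0.5 means average-sized, below 0.5
contracted, above 0.5 expanded.  The Tukey box summary of a species' F values
over all conserved families shows whether its genome is dominated by
contraction.
"""

from ortholoss import conserved_orthogroups, f_index, f_summary
from ortholoss.family_matrix import GeneCountMatrix
from ortholoss.simulate import DEFAULT_PANEL, DEFAULT_REFERENCE, simulate_family_matrix
import pandas as pd

# a family with equal counts everywhere: every species sits exactly at the mean
toy = GeneCountMatrix(pd.DataFrame([[2, 2, 2]], index=["OG1"], columns=["a", "b", "c"]))
print("F at the family mean:", f_index(toy, "OG1", "a"))  # exactly 0.5

matrix, _ = simulate_family_matrix(n_orthogroups=2000, seed=1)
conserved = conserved_orthogroups(matrix, DEFAULT_REFERENCE, DEFAULT_PANEL, 5)
box = f_summary(matrix, conserved, "Caus")
print(f"Caus F-index: median {box.median:.3f}, mean {box.mean:.3f}, "
      f"IQR [{box.q1:.3f}, {box.q3:.3f}]")
print(f"families below their all-species average size: "
      f"{100 * box.fraction_below_half:.1f}%")
# a median well under 0.5 and a high below-average fraction indicate
# genome-wide gene-family contraction in the parasite
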