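"""Detect frameshifts and premature stop codons in candidate CDSs.

Candidates are globally aligned to intact reference ORFs; maximal gap runs
with net length not divisible by three are frameshifts, and stop triplets
read in the (indel-shifted) reading frame before the terminal codon are
premature stops.
"""

from ortholoss import scan_pairs
from ortholoss.simulate import simulate_cds_pairs

pairs, truth = simulate_cds_pairs(n_pairs=30, cds_length_codons=100, seed=1)
reports = scan_pairs(pairs)

n_pseudo = sum(r.is_pseudogene for r in reports)
print(f"{n_pseudo}/{len(reports)} candidates classified as pseudogenes")

for report in reports[:6]:
    planted = truth.planted[report.pair_id]
    lesions = ", ".join(f"{l.kind}@{l.ref_position}({l.detail})" for l in report.lesions)
    print(f"{report.pair_id}: planted={planted.kind:>14s}  "
          f"detected=[{lesions or 'none'}]")
# each detected lesion carries its 1-based reference coordinate; a pair with
# any lesion is a pseudogene candidate, mirroring the frameshift-or-stop rule
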