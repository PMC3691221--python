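"""Accessibility profile of a protein C-terminus.

Scores the last 25 residues of a mitochondrially encoded protein with the
Janin accessibility scale in a 9-residue sliding window (edges fully
weighted), then min-max normalises to [0, 1]. Scores near 1 mark stretches
whose residues are typically solvent-exposed — candidate interaction sites;
scores near 0 mark buried, hydrophobic stretches.
"""

from mitocomp import JANIN_ACCESSIBILITY, normalize_profile, windowed_profile

cterm = "WFHDKALSASKSNELTSSEPKHLSH"  # a hydrophilic C-terminal tail
profile = normalize_profile(windowed_profile(cterm, JANIN_ACCESSIBILITY, window=9))

print("pos  aa  accessibility")
for i, (aa, score) in enumerate(zip(cterm, profile), start=1):
    bar = "#" * int(round(20 * score))
    print(f"{i:>3}  {aa}   {score:.2f} {bar}")
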