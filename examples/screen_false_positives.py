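"""Structurally corroborate predictions missing from the gold standard.

A predicted complex absent from every curated catalog is not automatically
wrong: its members may co-occur in a purified PDB structure.  This script
builds a small synthetic chain-map snapshot (protein -> pdb id, chain),
flags predictions with overlap score < 0.25 against every reference, and
reports member groups that share a structure and are not fragments of any
known complex.
"""
from dapgminer import (
    ChainMap,
    ComplexSet,
    false_positives,
    potential_complexes,
)

pred = ComplexSet([
    frozenset({"HSP82", "SBA1", "CPR6"}),   # not in the reference
    frozenset({"APL5", "APL6", "APM3"}),    # known complex
])
refs = ComplexSet([frozenset({"APL5", "APL6", "APM3", "APS3"})])

# synthetic SIFTS-style snapshot: HSP82 and SBA1 share structure 2cg9
chains = ChainMap((
    ("HSP82", "2cg9", "A"),
    ("HSP82", "2cg9", "C"),
    ("SBA1", "2cg9", "B"),
    ("CPR6", "1a33", "A"),
))

fps = false_positives(pred, refs, w=0.25)
print(f"{len(fps)} false-positive prediction(s):",
      [sorted(c) for c in fps])

for pc in potential_complexes(fps, chains, refs):
    members = " ".join(sorted(pc.member_proteins))
    print(f"potential complex in pdb {pc.pdb_id}: {members} "
          f"(from predicted complex #{pc.source_complex_index})")
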