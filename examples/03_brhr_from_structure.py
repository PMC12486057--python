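"""Score explanation quality against structural ground truth (BRHR).

Writes a tiny synthetic two-chain complex as a PDB file, extracts per-residue
minimum heavy-atom interaction distances, and computes the Binding Region Hit
Rate for a hand-made importance vector at t = 0.25.
"""

from pathlib import Path

import numpy as np

from tcrcross import binding_region_hit_rate, interaction_distances

# synthetic structure: epitope chain E approaches CDR3b chain B
SYNTHETIC_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  ALA E   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY E   2       4.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER E   3       9.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  TRP E   4      15.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  LEU B   1       0.000   3.000   0.000  1.00  0.00           C
ATOM      6  CA  VAL B   2       4.000   3.000   0.000  1.00  0.00           C
TER
END
"""

path = Path("example_output")
path.mkdir(exist_ok=True)
pdb = path / "synthetic_complex.pdb"
pdb.write_text(SYNTHETIC_PDB)

rd = interaction_distances(pdb, {"epitope": "E", "cdr3b": "B"},
                           direction=("cdr3b", "epitope"))
print("per-residue min heavy-atom distance of chain E to chain B (Angstrom):")
print(" ", np.round(rd.distances, 2))

good_scores = [0.9, 0.8, 0.1, 0.0]   # highlights the two closest residues
bad_scores = [0.0, 0.1, 0.8, 0.9]    # highlights the two farthest
for name, s in (("contact-aware", good_scores), ("inverted", bad_scores)):
    rate = binding_region_hit_rate(s, rd, t=0.5)
    print(f"BRHR(t=0.5) for {name} scores: {rate:.2f}")
print("1.0 means the top-ranked residues are exactly the closest contacts")
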