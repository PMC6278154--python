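"""Distance queries on a PDB-format structure.

Writes a tiny synthetic coordinate file, then asks the two questions the
analysis needs of a reference structure: the minimum heavy-atom distance
between two residues, and which positions of a candidate list fall within
5 A of a site (e.g. a catalytic triad).
"""

import tempfile
from pathlib import Path

from sdpnet import min_distance, proximity_report, read_structure

PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       3.000   3.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       4.000   4.000   0.000  1.00  0.00           C
ATOM      5  N   SER A   3      10.000  10.000  10.000  1.00  0.00           N
ATOM      6  CA  SER A   3      11.000  10.000  10.000  1.00  0.00           C
END
"""

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "toy.pdb"
    path.write_text(PDB)
    s = read_structure(path)

d12 = min_distance(s, [("A", 1)], [("A", 2)])
print(f"residue 1 to residue 2, min heavy-atom distance: {d12:.2f} A")

table = proximity_report(s, positions=[2, 3], site=[1], cutoff=5.0)
print(table.to_string(index=False))
# Residue 2 sits within the 5 A cutoff of the site residue; residue 3 is
# far outside and is not flagged.
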