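"""Worked example: recover the documented cleavage coordinates.

Chicken GSDMA is cleaved by caspase-1 after the aspartate of its linker
FASD tetrapeptide (P1 = residue 244); human GSDMD after FLTD at residue
275.  The stand-in sequences here are SYNTHETIC (built with the same
coordinate structure; the real NCBI records are not shipped), so what
this example demonstrates is the coordinate bookkeeping: alignment,
boundary projection, site extraction and classification must put the
reported P1 exactly where the cleavage site sits.
"""

from gsdmkit.worked_example import run_worked_example

for name, result in run_worked_example(seed=0).items():
    print(f"{name}:")
    print(f"  top caspase-1-like site: {result['tetrapeptide']} with P1 at "
          f"residue {result['p1_position']}")
    print(f"  downstream context: P1'={result['p1_prime']} P2'={result['p2_prime']}")
# expected: FASD with P1 at 244 (tetrapeptide residues 241-244) for the
# chicken GSDMA stand-in; FLTD with P1 at 275 for the human GSDMD stand-in
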