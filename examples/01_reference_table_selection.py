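"""Candidate selection from the packaged published linker table.

Loads the 52 seed genes and the 82 linker genes with their printed
ranking scores, applies the RS > 1 selection rule, and prints the
resulting candidate genes.  The strict inequality matters: two linkers
sit exactly at RS = 1 and are excluded.
"""

from seednet import load_reference_tables, select_candidates
from seednet.types import RankedGene

seeds, linker_rs = load_reference_tables()
ranked = [
    RankedGene(gene=g, rs=rs, rank=i + 1)
    for i, (g, rs) in enumerate(sorted(linker_rs.items(), key=lambda kv: (-kv[1], kv[0])))
]
candidates = select_candidates(ranked, rs_cutoff=1.0)

print(f"seed genes:          {len(seeds)}")
print(f"linker genes:        {len(linker_rs)}")
print(f"subnetwork nodes:    {len(seeds) + len(linker_rs)}")
print(f"max ranking score:   {max(linker_rs.values())}")
print(f"candidates (RS > 1): {', '.join(candidates)}")
# Each candidate is a linker gene whose summed (seed-doubled) edge
# weights exceed 1 -- the genes the network analysis nominates for
# follow-up as putative disease genes.
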