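"""Map a switch database into 2D chemical space.

Each pattern is instantiated on a hexaphyrin-like macrocycle template,
hashed into an ECFP fingerprint (radius 2, 2048 bits) and embedded with
t-SNE on Tanimoto/Jaccard distances.  Measures (here the number of
core-modified sets) are joined for coloring; the printed neighbor check
shows structural neighbors really are fingerprint neighbors.
"""

import numpy as np
import pandas as pd

from nloswitch import (
    HexaphyrinTemplate,
    count_core_modified_sets,
    embed,
    enumerate_space,
    fingerprint,
    hexaphyrin_scaffold,
    tanimoto,
)

scaffold = hexaphyrin_scaffold("26R")
template = HexaphyrinTemplate()

patterns = list(enumerate_space(scaffold, max_size=2000))[:60]
smiles = [template.to_smiles(p) for p in patterns]
print(f"example structure {patterns[10]}:\n  {smiles[10]}")

fps = [fingerprint(s) for s in smiles]
# structural neighbors (1 site changed) vs a distant pattern
print(f"Tanimoto({patterns[0]}, {patterns[1]}) = {tanimoto(fps[0], fps[1]):.3f}")
print(f"Tanimoto({patterns[0]}, {patterns[-1]}) = {tanimoto(fps[0], fps[-1]):.3f}")

measures = pd.DataFrame(
    {
        "pattern": [p.canonical_name for p in patterns],
        "n_core_modified": [
            count_core_modified_sets(p, scaffold) for p in patterns
        ],
    }
)
result = embed(fps, seed=1, perplexity=15.0, measures=measures)
print(f"\nembedded {len(result.coordinates)} patterns "
      f"(perplexity {result.perplexity}, seed {result.seed})")
print(result.coordinates.head(5).to_string(index=False))
# Writing result.coordinates to CSV gives the plotting-ready table:
# x, y, pattern, and any measure columns for coloring regions.
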