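"""Compare Bray-Curtis and Morisita sensitivity to sequencing depth.

Takes one community, sequences it deep, then rarefies a copy to one tenth
of the depth.  The two samples describe the same community, so an ideal
metric would call them identical.  Bray-Curtis on raw counts is pulled
apart by the depth difference; the Morisita index corrects for finite
sampling via its lambda term and barely moves.
"""

import numpy as np
import pandas as pd

from seqrunqc import TaxonCountTable, bray_curtis, hellinger_transform, morisita, rarefy

rng = np.random.default_rng(0)
proportions = rng.dirichlet(np.full(40, 0.4))
deep = rng.multinomial(30_000, proportions)
shallow = rarefy(deep, 3_000, rng)

t = TaxonCountTable(pd.DataFrame([deep, shallow], index=["deep", "shallow"],
                                 columns=[f"taxon{i}" for i in range(40)]))

bc_counts = bray_curtis(t).to_frame().iloc[0, 1]
bc_hell = bray_curtis(hellinger_transform(t)).to_frame().iloc[0, 1]
mor = morisita(t).to_frame().iloc[0, 1]

print(f"same community at 30k vs 3k reads:")
print(f"  Bray-Curtis on raw counts      : {bc_counts:.3f}")
print(f"  Bray-Curtis on Hellinger       : {bc_hell:.3f}")
print(f"  Morisita on raw counts         : {mor:.3f}")
print("\nA distance near 0 is correct here. Morisita is nearly unmoved by the "
      "10x depth difference, which is why the run diagnostics offer it "
      "alongside Bray-Curtis: a run flagged by Bray-Curtis but not by "
      "Morisita likely has a depth problem, not a community bias.")
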