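"""Fragment length distributions: the mononucleosomal mode and why size
selection enriches tumor signal.

Draws 100k fragments from each origin's default length model, prints the
histogram modes and the share of each origin inside the short-selection
window [90, 150] bp.  The ratio of those shares is the enrichment factor
that size selection applies to the tumor-derived fraction.
"""

import numpy as np

from cfmeth import sample_fragment_length

rng = np.random.default_rng(0)
nontumor = sample_fragment_length("nontumor", rng, size=100_000)
tumor = sample_fragment_length("tumor", rng, size=100_000)

for name, lengths in (("non-tumor", nontumor), ("tumor", tumor)):
    mode = int(np.argmax(np.bincount(lengths)))
    short = ((lengths >= 90) & (lengths <= 150)).mean()
    print(f"{name:>9}: mode {mode} bp, mean {lengths.mean():6.1f} bp, "
          f"{100 * short:5.1f}% inside the 90-150 bp window")

enrich = ((tumor >= 90) & (tumor <= 150)).mean() / ((nontumor >= 90) & (nontumor <= 150)).mean()
print(f"\nsize selection multiplies the tumor fraction roughly {enrich:.1f}-fold")
# The non-tumor mode sits at 167 bp (nucleosome + linker); tumor fragments
# peak shorter, so restricting to 90-150 bp concentrates ctDNA.
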