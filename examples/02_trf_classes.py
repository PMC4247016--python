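"""Classify tRNA-derived fragments (tRFs) and check their CCA status.

tRFs fall into position/length classes on the mature tRNA: short
3'-anchored fragments (~19 nt, carrying the post-transcriptionally added
CCA), long 3'- and 5'-anchored fragments (30-36 nt, no CCA), halves
ending in the anticodon loop, and short D-loop/anticodon fragments.
"""

from srnascape import SyntheticConfig, generate
from srnascape.io_coverage import in_range
from srnascape.trf import classify_reads, trf_table

bundle = generate(SyntheticConfig(seed=17))
reads = in_range(bundle.all_reads())
records = classify_reads(reads, bundle.annotations.trnas)
print(f"{len(records)} fragments overlap the {len(bundle.annotations.trnas)} tRNA genes")

table = trf_table(records)
print(table.to_string(index=False))
# cca_present counts fragments whose READ sequence ends in CCA — for
# 3'-anchored classes this distinguishes mature-tRNA-derived short tRFs
# (CCA present) from precursor-derived long 3'-tRFs (CCA absent).
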