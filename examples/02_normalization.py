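"""CPM and relative transcript abundance on a tiny two-gene matrix.

CPM rescales each sample to a library of one million; relative abundance
expresses each transcript as a percent of its gene's total in that sample,
the quantity isoform-usage questions care about.
"""

import pandas as pd

from isoviz import ExpressionTable, normalize_cpm, normalize_relative_abundance

long = pd.DataFrame({
    "transcript_id": ["T1", "T2", "T3"] * 2,
    "sample_id": ["s1"] * 3 + ["s2"] * 3,
    "raw_count": [30.0, 70.0, 100.0, 10.0, 10.0, 80.0],
})
gene_of = {"T1": "G1", "T2": "G1", "T3": "G2"}  # T1+T2 share a gene

expr = normalize_relative_abundance(normalize_cpm(ExpressionTable(long)), gene_of)
print(expr.df.to_string(index=False))
# cpm sums to 1e6 within each sample; relative_abundance sums to 100 within
# each (gene, sample): T1 is 30% of G1 in s1 but 50% in s2 — an isoform
# switch invisible at the gene level.
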