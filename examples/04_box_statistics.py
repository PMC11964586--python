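"""Tukey box statistics exactly as the expression panels draw them.

Median, linear-interpolation quartiles, whiskers to the most extreme data
points within 1.5 x IQR of the box, and everything beyond as outliers.
"""

import pandas as pd

from isoviz import ExpressionTable, compute_box_stats

values = [1, 2, 3, 4, 100]
expr = ExpressionTable(pd.DataFrame({
    "transcript_id": "T1",
    "sample_id": [f"s{i}" for i in range(len(values))],
    "raw_count": [float(v) for v in values],
    "condition": "AD",
}))

(box,) = compute_box_stats(expr, "raw_count", ["T1"], "condition")
print(f"values        {values}")
print(f"median        {box.median}")
print(f"quartiles     ({box.lower_quartile}, {box.upper_quartile})  IQR {box.iqr}")
print(f"whiskers      [{box.whisker_low}, {box.whisker_high}]")
print(f"outliers      {list(box.outliers)}")
# The upper fence is Q3 + 1.5*IQR = 7, so the whisker stops at 4 (the most
# extreme observation inside the fence) and 100 is flagged as an outlier.
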