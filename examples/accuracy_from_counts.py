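"""Accuracy-assessment arithmetic from a validation contingency table.

Feeds a 2 x 2 actual-vs-predicted pixel count table (here: an OC-SVM
validation on 860 pixels, 441 actual target + 419 actual other) through the
evaluation module and prints every standard metric.
"""

import numpy as np

from ocweed import ConfusionTable, metrics
from ocweed.scene_sim import TARGET, OTHER

table = ConfusionTable(np.array([[416, 25],   # actual target weed
                                 [9, 410]]))  # actual other vegetation
report = metrics(table).rounded(2)

print(report.to_text("OC-SVM validation"))
print()
print(f"omission error (target):   {report.omission_error[TARGET]}%  "
      "— actual weed pixels the map missed")
print(f"commission error (target): {report.commission_error[TARGET]}%  "
      "— other-vegetation pixels wrongly mapped as weed")
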