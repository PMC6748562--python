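"""Watch identification power grow as the reference library accumulates.

Recomputes the identification rate for the same specimens against yearly
library snapshots under both access views: SLBR (species-level records,
public or not) and PRBD (published records only).  The identified
percentage can only rise year over year, and the SLBR curve dominates
PRBD whenever the public records are a subset of the species-level ones —
the access-gap signature.
"""

from barcodeaudit import PRBD, SLBR, identification_timeseries
from examples_common import small_study

records, queries, config = small_study()

table = identification_timeseries(queries, records, list(config.years), [SLBR, PRBD])
print(table.to_string(index=False))
print()
gap = table.pivot(index="year", columns="view", values="pct_identified")
print("access gap (SLBR - PRBD) per year, in percentage points:")
print((gap["SLBR"] - gap["PRBD"]).round(1).to_string())
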