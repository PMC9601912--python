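"""Recompute the bundled reference study's inferential tables.

The package bundles the printed group statistics (n, mean, SD) of a
published 12-patient vs 12-control spiral-test study together with its
printed independent-samples t-test tables.  The t-test cells are pure
functions of the summaries, so they can be recomputed and compared cell by
cell; all 206 comparable cells match to one unit in the last printed digit
(four documented source misprints are flagged and excluded, and the Levene
columns need unpublished raw data).
"""

from spiraldst.reference_tables import format_check_report, recompute_all

checks = recompute_all()
report = format_check_report(checks)
# print the patients-vs-controls block and the closing summary
lines = report.splitlines()
print("\n".join(lines[:4]))
print("\n".join(l for l in lines if l.startswith("health")))
print()
print("\n".join(lines[-7:]))
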