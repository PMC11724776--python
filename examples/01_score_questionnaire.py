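"""Score a small administered questionnaire table.

Builds three children by hand — one highly adherent, one average, one
non-adherent — and prints their per-item points, totals, quartile bands
(Q1 0-8, Q2 9-11, Q3 12-13, Q4 14-18) and the low/high adherence class
(cutoff 10 points).
"""

import pandas as pd

from med4child import score_table

rows = [
    # highly adherent: olive oil main fat, plenty of vegetables/fruit/
    # fish/nuts, almost no sweets or processed food
    dict(child_id="adherent", q01=1, q02=4.0, q03=2.5, q03_raw=3, q04=3.0,
         q05=5, q06=1.5, q07=3, q08=4, q09=3.5, q10=1, q11=2.5, q12=1,
         q13=0.3, q14=0.5, q15=0.5, q16=0.5, q17=1, q18=0),
    # middling habits
    dict(child_id="average", q01=1, q02=2.0, q03=1.0, q03_raw=1, q04=1.5,
         q05=2, q06=1.0, q07=2, q08=2, q09=1.0, q10=1, q11=1.0, q12=1.5,
         q13=0.5, q14=1.0, q15=2.0, q16=1.5, q17=1, q18=0.5),
    # non-adherent: little Mediterranean food, frequent sweets and sodas
    dict(child_id="low", q01=0, q02=0.5, q03=0.5, q03_raw=0, q04=0.5,
         q05=1, q06=0.3, q07=1, q08=1, q09=0.0, q10=0, q11=0.5, q12=4,
         q13=1.5, q14=5.0, q15=4.0, q16=3.0, q17=4, q18=3),
]
scored = score_table(pd.DataFrame(rows))

print(scored.to_string(index=False))
print()
print("Each pt column is one item's point (1 = criterion satisfied); the")
print("total is their sum over the 18 items, so 'adherent' lands in Q4")
print("with high adherence while 'low' stays in Q1.")
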