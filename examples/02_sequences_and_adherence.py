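"""Encode one patient's care events into three state sequences and score
guideline adherence.

The three dimensions are HCP contact (quarterly, states O/N), diagnostics
(quarterly, states N/H/B/HB for HbA1c and a >=200 test-strip prescription)
and screening (annual, combinations of R/C/T). Perfect adherence means
contact + HbA1c + strips in all 12 quarters and, over 3 years, >=2
retinopathy, >=2 thyroid and >=1 cholesterol screen years.
"""

from datetime import date

import pandas as pd

from careseq import assess_adherence, build_timeline, encode_dimension

WINDOW = (date(2017, 1, 1), date(2019, 12, 31))

rows = []
for q in range(12):
    y, m = 2017 + q // 4, 3 * (q % 4) + 1
    rows.append(("p1", f"{y}-{m:02d}-10", "OUTPATIENT_CONTACT", None, "outpatient"))
    if q != 5:  # one quarter misses the HbA1c measurement
        rows.append(("p1", f"{y}-{m:02d}-12", "HBA1C", None, "outpatient"))
    rows.append(("p1", f"{y}-{m:02d}-15", "STRIPS_RX", 250, "outpatient"))
for y in (2017, 2018):
    rows.append(("p1", f"{y}-06-01", "RETINOPATHY_SCREEN", None, "outpatient"))
    rows.append(("p1", f"{y}-06-02", "THYROID_SCREEN", None, "outpatient"))
rows.append(("p1", "2018-06-03", "CHOLESTEROL_SCREEN", None, "outpatient"))
events = pd.DataFrame(rows, columns=["patient_id", "date", "event_code", "quantity", "setting"])

quarters = build_timeline(WINDOW, "quarter")
years = build_timeline(WINDOW, "year")
seqs = [
    encode_dimension(events, "hcp_contact", quarters),
    encode_dimension(events, "diagnostics", quarters),
    encode_dimension(events, "screening", years),
]
for s in seqs:
    print(f"{s.dimension:12s} {'-'.join(s.states)}")

result = assess_adherence(seqs)
print("requirement met:", result["requirements"])
print("counts:", result["counts"])
print("perfect adherence:", result["perfect"])
# one missing HbA1c quarter (state B in 2018-Q2) is enough to break perfection
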