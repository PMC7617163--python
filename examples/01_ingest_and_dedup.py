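"""Ingest citations from RIS, normalise them, and remove duplicate records.

Two of the three records below describe the same publication retrieved
from different databases (same DOI, differently cased title); the
deduplicator merges them and keeps the record with an abstract.
"""

import tempfile
from pathlib import Path

from soles import deduplicate, read_citations

RIS = """\
TY  - JOUR
TI  - Spatial memory deficits in a transgenic cohort
AB  - Behavioural testing revealed deficits.
AU  - Vega, M.
PY  - 2021
DO  - https://doi.org/10.99/EXAMPLE.1
DB  - pubmed
ID  - 101
ER  -

TY  - JOUR
TI  - SPATIAL MEMORY DEFICITS IN A TRANSGENIC COHORT
AU  - Vega, M.
PY  - 2021
DO  - 10.99/example.1
DB  - wos
ID  - W-55
ER  -

TY  - JOUR
TI  - An unrelated electrophysiology report
AU  - Okafor, N.
PY  - 2020
DO  - 10.99/example.2
DB  - pubmed
ID  - 102
ER  -
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "records.ris"
    path.write_text(RIS)
    citations = read_citations(path, format="ris")

print(f"read {len(citations)} records; DOIs normalised, e.g. {citations.records[0].doi}")

kept, duplicates = deduplicate(citations)
print(f"after deduplication: {len(kept)} unique records")
for group in duplicates.groups:
    print(f"  merged {sorted(group)} -> kept {duplicates.kept[group]}")
# The kept uid is the PubMed record: the keep rule prefers the member
# that carries an abstract, then one with a DOI, then the smallest uid.
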