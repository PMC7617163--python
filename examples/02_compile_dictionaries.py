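"""Compile a term list into boundary-anchored match expressions.

Dictionary terms are expanded over separator and case variants, then
anchored so letters AND digits act as word characters: the gene "APP"
must not fire inside "PAPP" or "APP23", while slash-delimited model
names like "APP/PS1" still match.
"""

from soles import TermEntry, compile_term, expand_variants
from soles.tagging import count_matches

variants = expand_variants("3xTg-AD")
print(f"'3xTg-AD' expands to {len(variants)} surface variants, e.g.:")
print("  ", [v for v in variants if "×" in v][:4])
# The multiplication-sign forms mean the dictionary matches "3 × Tg" as
# printed in journals, not just the compact "3xTg-AD".

app = compile_term(TermEntry("APP", "model"))
for text in ("the APP gene", "PAPP", "APP23", "APP/PS1 mice"):
    print(f"  APP matches in {text!r}: {count_matches(app, text).count}")
# 1 / 0 / 0 / 1 — the digit boundary blocks APP23, the letter boundary
# blocks PAPP, and the slash is a legitimate word boundary.

mwm = compile_term(TermEntry("Morris water maze", "outcome",
                             synonyms=["water maze", "MWM", "Morris maze"]))
result = count_matches(mwm, "The Morris water maze (MWM) was used")
print(f"  outcome mentions counted: {result.count} (longest synonym wins per span)")
# 2, not 3: "water maze" inside "Morris water maze" is not double-counted.
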