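"""Dictionary-based candidate retrieval.

Matches a small concept/synonym list against a toy corpus in the three
matching modes and prints which records would be proposed as nano
candidates for human review.
"""

from nanoct import TermList, match_terms, propose_candidates
from nanoct.ctgov_io import CTRecord, LabeledCorpus

corpus = LabeledCorpus(
    records=[
        CTRecord("NCT00000001", "Nanoparticle albumin-bound paclitaxel"),
        CTRecord("NCT00000002", "A novel nanosuspension of itraconazole"),
        CTRecord("NCT00000003", "Superparamagnetic iron oxide imaging"),
        CTRecord("NCT00000004", "Conventional oral metformin tablets"),
    ],
    labels=["nano", "nano", "nano", "non-nano"],
)

terms = TermList(concepts=(
    ("C0597131", ("nanoparticle", "nano")),
    ("C0302583", ("iron oxide", "ferumoxytol")),
))

for mode in ("token", "prefix", "phrase"):
    report = match_terms(corpus, terms, mode=mode)
    print(f"{mode:>6}: matched {sorted(report.matched_record_ids)}")
# 'prefix' also catches 'nanosuspension' via the 'nano' prefix — the kind
# of search a registry's own engine typically cannot do.

report = match_terms(corpus, terms, mode="prefix")
print("candidates (>=1 concept):", sorted(propose_candidates(report, 1)))
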