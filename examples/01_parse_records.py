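"""Parse study-record XML into a labeled corpus.

Builds two tiny registry-style records in memory, parses their free-text
fields, joins them with a label table, and prints the assembled corpus.
"""

from nanoct import assemble_corpus, parse_ct_record

XML_NANO = """
<clinical_study>
  <id_info><nct_id>NCT00000001</nct_id></id_info>
  <brief_title>Liposomal Doxorubicin in Breast Cancer</brief_title>
  <brief_summary><textblock>
    A phase II study of 50 mg liposomal doxorubicin nanoparticles.
  </textblock></brief_summary>
  <condition>Breast Cancer</condition>
</clinical_study>
"""

XML_CTRL = """
<clinical_study>
  <id_info><nct_id>NCT00000002</nct_id></id_info>
  <brief_title>Aspirin for Cardiovascular Prevention</brief_title>
  <brief_summary><textblock>Daily low-dose aspirin.</textblock></brief_summary>
</clinical_study>
"""

records = [parse_ct_record(x) for x in (XML_NANO, XML_CTRL)]
labels = {"NCT00000001": "nano", "NCT00000002": "non-nano"}
corpus = assemble_corpus(records, labels)

for rec, label in zip(corpus.records, corpus.labels):
    print(f"{rec.nct_id} [{label}]")
    for line in rec.text.split("\n"):
        print(f"  | {line}")
# Each record's text is the newline-joined character content of the
# configured free-text fields, in document order.
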