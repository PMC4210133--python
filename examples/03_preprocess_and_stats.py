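"""Preprocessing pipeline and corpus feature statistics.

Shows the fixed normalization order (digit masking, lowercasing,
stop-word and short-token removal, Porter stemming), then summarizes
unigram/bigram counts over a small corpus the way corpus descriptions
usually tabulate them (per-document totals, unique counts, document
frequencies).
"""

from nanoct import corpus_feature_stats, normalize, text_to_bag, tokenize

text = "Doxil (liposomal doxorubicin), 50 mg in 100 ml."
raw = tokenize(text)
norm = normalize(raw)
print("raw tokens:       ", [t for t in raw.tokens if t != "\n"])
print("normalized tokens:", [t for t in norm.tokens if t != "\n"])
# '50' masks to '##' and is dropped by the length filter; '100' masks to
# '###' (length 3) and survives; 'liposomal' stems to 'liposom'.

docs = [
    "Liposomal doxorubicin nanoparticles for breast cancer.",
    "Iron oxide nanoparticles as contrast agent.",
    "Aspirin versus placebo in cardiovascular prevention.",
]
for n in (1, 2):
    bags = [text_to_bag(d, n=n) for d in docs]
    stats = corpus_feature_stats(bags)
    tot = stats["per_document_total"]
    print(f"\n{n}-grams: {stats['n_features']} distinct features; "
          f"per-doc totals min {tot['min']} max {tot['max']} "
          f"mean {tot['mean']:.2f} sd {tot['sd']:.2f}; "
          f"mean docs per feature {stats['mean_docs_per_feature']:.2f}")
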