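"""The four bag-of-words representations on a three-document corpus.

Prints the dense matrices for binary, frequency, IDF and TF-IDF
weighting.  Note the feature occurring in every document ('common') gets
idf = ln(N/df) = ln(1) = 0 and vanishes from the IDF-based schemes.
"""

import numpy as np

from nanoct import build_vocabulary, weight
from nanoct.preprocess import NGramBag

bags = [
    NGramBag(1, {"liposom": 2, "common": 1}),
    NGramBag(1, {"liposom": 1, "aspirin": 1, "common": 2}),
    NGramBag(1, {"aspirin": 3, "common": 1}),
]
vocab = build_vocabulary(bags)
print("features:", vocab.features, "df:", vocab.df, "N:", vocab.N)

np.set_printoptions(precision=4, suppress=True)
for scheme in ("binary", "frequency", "idf", "tfidf"):
    m = weight(bags, vocab, scheme)
    print(f"\n{scheme}:\n{m.matrix.toarray()}")

m = weight(bags, vocab, "tfidf", normalized=True)
print("\nnormalized tfidf (unit L2 rows):")
print(m.matrix.toarray())
print("row norms:", np.linalg.norm(m.matrix.toarray(), axis=1))
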