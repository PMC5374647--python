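"""Gene word vectors from free-text annotations.

Builds tf-idf word vectors for three genes from short functional
descriptions and prints each gene's top tokens. Related genes (TP53, its
inhibitor MDM2) share vocabulary; an unrelated gene (TTN, a muscle
protein) does not — the premise that lets tumors with different mutated
genes look similar in word space.
"""

from oncothemes import GeneText, build_corpus

texts = [
    GeneText(
        "TP53",
        ["TP53", "p53"],
        "p53 is a tumor suppressor regulating apoptosis and dna repair; "
        "mutation of p53 drives many cancers; p53 activates transcription "
        "of cell cycle arrest genes",
    ),
    GeneText(
        "MDM2",
        ["MDM2"],
        "mdm2 is a proto-oncogene that inhibits p53 by ubiquitin mediated "
        "degradation; amplification of mdm2 suppresses apoptosis in tumors",
    ),
    GeneText(
        "TTN",
        ["TTN", "titin"],
        "titin is a giant sarcomere protein providing muscle elasticity; "
        "titin mutations cause cardiomyopathy and muscular dystrophy",
    ),
]

vocab, gene_docs = build_corpus(texts, vocab_size=20_000, vector_size=200)

print(f"vocabulary: {len(vocab)} stemmed tokens over {vocab.corpus_size} gene documents\n")
for gid, gdoc in gene_docs.items():
    top = sorted(gdoc.selected, key=lambda t: -gdoc.tfidf[t])[:6]
    pretty = ", ".join(f"{t}={gdoc.tfidf[t]:.2f}" for t in top)
    print(f"{gid:5s} top tf-idf tokens: {pretty}")

tp53 = set(gene_docs["TP53"].selected)
print("\nshared tokens TP53 & MDM2:", sorted(tp53 & set(gene_docs["MDM2"].selected)))
print("shared tokens TP53 & TTN: ", sorted(tp53 & set(gene_docs["TTN"].selected)))
# Aliases ("p53", "titin") carry each gene's maximum tf-idf score, so an
# alteration is never reduced to an anonymous bag of generic words.
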