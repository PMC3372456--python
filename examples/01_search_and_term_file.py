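"""First-round BM25 passage retrieval and the per-passage term file.

Generates a small synthetic collection, extracts the query keywords,
retrieves the top passages, and prints the head of the run alongside which
query stems each retrieved passage contains.
"""

from termassoc import (
    BM25Params,
    extract_keywords,
    generate_term_file,
    index_corpus,
    search,
)
from termassoc.synthetic import SyntheticSpec, generate_collection

coll = generate_collection(SyntheticSpec(n_docs=40), seed=7)
index = index_corpus(coll.corpus, granularity="paragraph")
keywords = extract_keywords(coll.topic)
print(f"query {coll.topic.topic_id}: keywords = {' '.join(keywords.keywords)}")

run = search(index, keywords, BM25Params(k1=1.2, b=0.75), n_out=20)
terms = generate_term_file(run, keywords, index)

print(f"\ntop {len(run)} of {index.n_passages} indexed passages "
      "(weight = BM25 score; offset/length in characters):")
for entry, tf_entry in zip(run[:5], terms[:5]):
    stems = " ".join(sorted(tf_entry.found_stems))
    print(f"  rank {entry.rank}: doc {entry.doc_id} [{entry.offset},"
          f"{entry.offset + entry.length}) weight {entry.weight:.3f}  >>{stems}")

# Passages containing several distinct query keywords score highest: the
# weight sums one BM25 term contribution per matching keyword.
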