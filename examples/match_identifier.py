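"""Regex prefilter: which databases could a bare identifier come from?

Identifier grammars overlap across databases, so pattern matching alone
returns candidate sets, not unique answers — the motivation for the
machine-learning classifier.
"""

from bioidkit import default_registry

registry = default_registry()

for query in ["CHEMBL25", "ENSG00000164197", "HGNC:27752", "NM_001354609", "XYZZY-42"]:
    hits = registry.match(query)
    print(f"{query:18s} -> {hits if hits else 'no pattern matches'}")

# CHEMBL25 matches more than one class: a ChEMBL accession is also a legal
# gene-symbol surface form.  The classifier resolves such ambiguity from the
# statistics of character positions rather than from the pattern alone.
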