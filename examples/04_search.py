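"""The three query modes: exact (tautomer- and ratio-insensitive),
substructure (no false negatives) and similarity (Tanimoto-ranked)."""

from ucd import Registry, exact_search, similarity_search, substructure_search

META = {"project": "SRCH", "scientist": "alice"}

reg = Registry()
reg.add_user("alice", "submitter")
reg.add_user("ruth", "registrar")

for smiles in ["N#CCC(=O)O", "CC(=O)Oc1ccccc1C(=O)O", "O=c1cccc[nH]1",
               "CC(=O)Nc1ccc(O)cc1", "CCO", "c1ccc2ccccc2c1"]:
    sub = reg.submit("alice", smiles, metadata=META)
    reg.decide_submission("ruth", sub.id, True)

# exact search finds a molecule through any tautomer drawing
hits = exact_search(reg, "Oc1ccccn1")  # the 2-hydroxypyridine drawing
print("exact  Oc1ccccn1      ->", [h.molecule_code for h in hits],
      "(registered as the 2-pyridone tautomer)")

# substructure: all molecules containing a nitrile / an aromatic ring
for query in ["C#N", "c1ccccc1"]:
    hits = substructure_search(reg, query)
    print(f"sub    {query:14s} -> {[h.molecule_code for h in hits]}")

# similarity: ranked Tanimoto over 2048-bit path fingerprints
for hit in similarity_search(reg, "CC(=O)Oc1ccccc1C(=O)O", threshold=0.3):
    print(f"sim    {hit.molecule_code}  score={hit.score:.3f}")
# score 1.0 means identical fingerprints; unrelated scaffolds score near 0.
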