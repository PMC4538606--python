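"""Disease semantic similarity from a tiny MeSH-style DAG.

Two sibling diseases under a common parent share only the root of their
ancestor graphs; with contribution decay 0.5 their similarity is exactly
(0.5 + 0.5) / (1.5 + 1.5) = 1/3.  A disease compared with itself always
scores 1.
"""

import networkx as nx

from hglda import EntityId, build_disease_dag, semantic_similarity, semantic_similarity_matrix

term = lambda s: EntityId("mesh_term", s)
disease = lambda s: EntityId("disease", s)

dag = nx.DiGraph([(term("neoplasms"), term("breast neoplasms")),
                  (term("neoplasms"), term("lung neoplasms"))])
mapping = {disease("breast cancer"): {term("breast neoplasms")},
           disease("lung cancer"): {term("lung neoplasms")}}

breast = build_disease_dag(disease("breast cancer"), mapping, dag, delta=0.5)
print("breast cancer DAG contributions:",
      {t.label: c for t, c in sorted(breast.contribution.items())})
print(f"semantic value DV = {breast.semantic_value}")

s1 = semantic_similarity_matrix(sorted(mapping), mapping, dag)
print("S1 matrix over", [e.label for e in s1.entities])
print(s1.values)
print(f"sibling similarity = {s1.values[0, 1]:.4f}  (expected 1/3)")
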