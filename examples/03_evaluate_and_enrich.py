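"""Score a predicted catalog and test one complex for functional enrichment.

Shows overlap-score matching (Sn/Sp/F-measure) between two small hand-made
catalogs, and the hypergeometric tail probability that a complex contains
this many members of a functional group by chance.
"""

import pollinet as pn
from pollinet.io_formats import ComplexCatalog

reference = ComplexCatalog(complexes=[
    frozenset({"a", "b", "c"}), frozenset({"d", "e", "f"}), frozenset({"g", "h"}),
])
predicted = ComplexCatalog(complexes=[
    frozenset({"a", "b", "c"}),            # perfect match
    frozenset({"d", "e", "x"}),            # overlap score 4/9 >= 0.2: a match
    frozenset({"p", "q"}),                 # spurious
])

m = pn.match_catalogs(predicted, reference, os_threshold=0.2)
print(f"TP={m.tp} FP={m.fp} FN={m.fn}  Sn={m.sn:.3f} Sp={m.sp:.3f} F={m.f_measure:.3f}")
print(f"perfect matches (overlap score exactly 1): {m.perfect}")

# Of a 20-protein network, 5 proteins carry some functional annotation; a
# predicted 4-protein complex contains 3 of them.  How surprising is that?
query = pn.EnrichmentQuery(k=3, n_total=20, c_size=4, f_size=5)
p = pn.hypergeom_pvalue(query)
print(f"enrichment p-value = {p:.5f}  ({'significant' if p < 0.01 else 'not significant'} at 0.01)")
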