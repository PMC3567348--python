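"""Gene-set enrichment with a custom reference: the stress-reporter library.

Asks which functional categories are over-represented among 24
activated reporter ORFs when the reference is the whole 122-member
stress-response reporter library (not the genome) — the right null when
the assay only ever probed those reporters.
"""

import fitscreen
from fitscreen.enrichment import AnnotationDB, enrich, read_gmt

lib = read_gmt(fitscreen.stress_library_path())
go = read_gmt(fitscreen.go_stress_subsets_path())
db = AnnotationDB(categories=go.categories, universe=lib.universe)

activated = [
    "GLK1", "TRX2", "ATM1", "SNQ2", "BPT1", "QDR2", "TPO1", "AQR1", "YRM1",
    "HSP78", "SSA4", "SSA3", "HSP104", "HSP42", "SSE2", "SLN1", "MSB2",
    "ATF2", "OGG1", "APN2", "RAD51", "HTA2", "CTT1", "GSH1",
]

rows = enrich(activated, db, reference=lib.universe, threshold=0.01)
print(rows[["category", "name", "p", "k", "K", "n", "N"]].to_string(index=False))
# p is the raw hypergeometric upper tail P(X >= k) of drawing k category
# members in an n-gene test set from an N-gene reference containing K;
# a fully-hit 3-gene category here gives p ~ 0.007.
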