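"""Score ratio values (SRV) and the homology screen.

The SRV of a hit is its bit score divided by the query's self-hit bit score,
so identical sequences score 1.0 and the threshold does not need to be
relaxed for very short proteins.  Queries whose best reference hit reaches
SRV >= 0.7 are kept; hypothetical ones inherit the reference's product.
"""

from pepfam import ProteinRecord, ScoringScheme, homology_screen, local_align, self_scores
from pepfam.similarity import compute_srv

scheme = ScoringScheme()  # BLOSUM62, gap 11/1, lambda 0.267, K 0.041

reference = ProteinRecord("ref1", "MKRWLVTAEGDNQSHPYFCAMKRWLVTAEG", product="cold-shock protein")
near = ProteinRecord("q_near", "MKRWLVTAEGDNQSHPYFCAMKRWLVTAEG", product="hypothetical protein")
far = ProteinRecord("q_far", "WWPPGGHHCCWWPPGGHHCCWWPPGGHHCC")

for q in (near, far):
    row = local_align(q, reference, scheme)
    srv = compute_srv(row, self_scores([q], scheme)) if row.alignment_length else 0.0
    print(f"{q.id}: bit score {row.bit_score:.1f}, SRV {srv:.3f}")

accepted, reannotated = homology_screen([near, far], [reference], scheme, min_srv=0.7)
print("accepted:", [a.id for a in accepted])
print("re-annotated:", reannotated)
# q_near is identical to the reference (SRV 1.0) so it passes the screen and,
# being 'hypothetical', inherits the reference product; q_far has no
# E-value-passing hit and is rejected.
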