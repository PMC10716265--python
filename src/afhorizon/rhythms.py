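"""Rhythm labels shared across modules.

AF groups atrial fibrillation and atrial flutter under a single label;
SVT and AVB stand for the non-AF abnormal rhythms tracked by the rhythm
feature family (supraventricular tachycardia, atrioventricular block).
Artifact segments are labeled, never dropped, so every sample of a record
belongs to exactly one rhythm episode.
"""

SINUS = "SINUS"
AF = "AF"
SVT = "SVT"
AVB = "AVB"
ARTIFACT = "ARTIFACT"

RHYTHMS = (SINUS, AF, SVT, AVB, ARTIFACT)

# WFDB-style aux rhythm-change labels used by the text annotation format
WFDB_AUX = {SINUS: "(N", AF: "(AFIB", SVT: "(SVTA", AVB: "(BII", ARTIFACT: "(NOISE"}
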