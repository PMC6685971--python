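"""The weighted voting rule, worked by hand.

A subset voting OSA contributes +1 x its OOB sensitivity; a subset
voting non-OSA contributes -1 x its OOB specificity; the final decision
d is the mean. With six perfect subsets (100% sensitivity and
specificity) a unanimous OSA vote lands exactly at +1 and a unanimous
non-OSA vote at -1.
"""

from awakeosa import weighted_decision

unanimous_osa = weighted_decision([+1.0 * 1.0] * 6)
unanimous_non = weighted_decision([-1.0 * 1.0] * 6)
print(f"six unanimous OSA votes, perfect weights:     d = {unanimous_osa.d:+.3f}")
print(f"six unanimous non-OSA votes, perfect weights: d = {unanimous_non.d:+.3f}")

mixed = weighted_decision([+0.84, -0.875, +0.80])
print(f"votes (+0.84, -0.875, +0.80):                 d = {mixed.d:+.3f} -> {mixed.call}")
# (0.84 - 0.875 + 0.80) / 3 = +0.255: a weak OSA call, below the 0.7
# high-confidence threshold.
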