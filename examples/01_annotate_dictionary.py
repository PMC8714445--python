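"""Automatic BIES annotation of a symptom dictionary.

Builds a tiny dictionary of standard symptom phrases and shows the
automatic position labels: Single for one-component phrases, otherwise
Begin / Intermediate / End.  These labels are the only supervision the
whole method uses — no corpus annotation exists anywhere.
"""

from comd import annotate_dictionary
from comd.dictionary import phrases_from_lines

lines = [
    "fever",
    "persistent low-back pain",
    "chest distress",
    "intermittent urinary protein",
]
phrases = phrases_from_lines(lines, granularity="word")

for annotated in annotate_dictionary(phrases):
    pairs = "  ".join(f"{c}/{l}" for c, l in annotated.items())
    print(pairs)

print()
print("Each component is tagged by where it sits in its phrase;")
print("counting these tags across a large dictionary yields each")
print("component's position multinomial (pi_B, pi_I, pi_E, pi_S).")
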