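"""Maximum-likelihood position multinomials.

Reproduces the worked example: a component observed 60 times at the
beginning of phrases and 12 times in the middle has n = 72 trials and
MLE probabilities (0.83, 0.17, 0, 0) — so it may open a phrase or sit
inside one, but can never close a phrase or stand alone.
"""

from comd import SymptomPhrase, accumulate_position_counts, annotate_dictionary

phrases = [
    SymptomPhrase(raw="", components=("intermittent", f"tail{i}"))
    for i in range(60)
] + [
    SymptomPhrase(raw="", components=(f"head{i}", "intermittent", f"tail{i}"))
    for i in range(12)
]

table = accumulate_position_counts(annotate_dictionary(phrases))
stats = table["intermittent"]

print(f"counts (B, I, E, S) = {stats.counts}")
print(f"trials n            = {stats.n}")
print("MLE (pi_B, pi_I, pi_E, pi_S) =",
      tuple(round(p, 2) for p in stats.probs))
print("permissible labels  =",
      sorted(l.value for l in stats.permissible_labels()))
print()
print("Zero-count positions have probability exactly 0: the component")
print("is never allowed to take those labels during recognition.")
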