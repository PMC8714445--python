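"""Extraction from noisy colloquial sentences.

Generates a synthetic study (dictionary + noisy corpus), trains the full
model, and walks through one sentence: candidate labels, the selected
segmentation, and the final phrase after utility filtering removes the
colloquial fillers sitting inside the span.
"""

from comd import ExtractorConfig, assign_labels, preprocess
from comd.benchmark import study_config, train_study_model
from comd.simulate import generate

data = generate(study_config(seed=3))
model = train_study_model(data, seed=3)

# pick a record whose span has fillers inserted inside it
rid, tokens = next(
    (rid, toks) for rid, toks in data.sentences
    if data.gold[rid] and any(t.startswith("x") for t in toks)
)
text = " ".join(tokens)
print(f"record {rid}: {text}")
print(f"gold phrases: {data.gold[rid]}")

(sentence,) = preprocess(text, record_id=rid, filters=model.filters)
candidates = assign_labels(sentence, model.stats, model.interaction)
print("\ncandidate labels per token:")
for token, labels in zip(sentence.tokens, candidates.sets):
    print(f"  {token:6s} {{{', '.join(sorted(l.value for l in labels))}}}")

for ex in model.extract_sentence(sentence, ExtractorConfig(delta=0.2)):
    print(f"\nextracted: {ex.phrase}")
    print(f"  token span {ex.source_span}, kept indices {ex.component_indices}")

print("\nFiller tokens (x..) may enter a span as Intermediate candidates,")
print("but their low interaction with the boundary components drops them;")
print("the kept components are concatenated into the phrase.")
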