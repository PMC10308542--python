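"""Train the time-reference stage on a synthetic corpus and classify
new sentences.

The model scores each sentence for future (FTR) and past (PTR) time
reference; probabilities at or above 0.5 become binary flags.
"""

import ftrclassify as f

corpus = f.generate_labeled_sentences(30, seed=7)
examples = [f.AnnotatedExample(s.text, s.time_ref) for s in corpus]
model, metrics = f.train_time_reference_model(examples, split=0.8, seed=0)

print("held-out metrics (20% of the labeled corpus):")
for label, m in metrics.items():
    print(f"  {label}: accuracy={m.accuracy:.3f} precision={m.precision:.3f} "
          f"recall={m.recall:.3f} F1={m.f1:.3f}")

for text in ["It will rain tomorrow", "It rained all day yesterday",
             "The sun is hot"]:
    pred = f.predict_time_reference(model, text)
    print(f"{text!r}: p_ftr={pred.p_ftr:.3f} p_ptr={pred.p_ptr:.3f} "
          f"is_ftr={pred.is_ftr} is_ptr={pred.is_ptr}")

# is_ftr = 1 means the sentence refers to future time; sentences with
# neither flag fall into the residual class (present reference, facts,
# statements of ability).
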