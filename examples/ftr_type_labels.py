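"""Assign future-referring sentences to tense/modal semantic categories.

Modal categories (certainty, obligation, desire, conditionality)
dominate tense; negated and mixed-certainty sentences are excluded
because keyword matching cannot recover their intended polarity.
"""

import ftrclassify as f

sentences = [
    "Tomorrow it will rain",                 # future tense
    "tomorrow it rains",                     # present tense (residual)
    "It could rain tomorrow",                # low-certainty modal verb
    "It will possibly rain tomorrow",        # low certainty, non-verbal
    "It could probably rain tomorrow",       # modal concord: both low flags
    "You must come tomorrow",                # deontic obligation
    "I hope it rains tomorrow",              # bouletic desire
    "Rain tomorrow is not possible",         # excluded: negation
    "There is definitely a possibility of rain tomorrow",  # excluded: mixed
]

labelsets = []
for text in sentences:
    labels = f.classify_ftr_type(text)
    if labels.excluded:
        print(f"{text!r}: EXCLUDED ({labels.exclusion_reason})")
    else:
        print(f"{text!r}: {', '.join(labels.active())}")
        labelsets.append(labels)

props = f.proportions_by_type(labelsets)
print("\ntype proportions over the retained sentences (sum to 1):")
for cat, p in sorted(props.items(), key=lambda kv: -kv[1]):
    if p:
        print(f"  {cat}: {p:.3f}")
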