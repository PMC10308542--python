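"""Resolve temporal expressions against posting time and compute the
sentence time horizon H(s): the mean signed day-distance of a
sentence's temporal references from its posting date.
"""

from datetime import datetime, timezone

import ftrclassify as f

posted = datetime(2020, 6, 10, 16, 0, tzinfo=timezone.utc)

for text in ["See you tomorrow!",
             "The launch is in 2 days and the review in 4 days.",
             "We moved here 30 days ago.",
             "I'm seeing her tonight."]:
    exprs = f.extract_temporal_expressions(text, posted)
    rec = f.sentence_horizon(exprs, posted, text)
    print(f"{text!r}")
    for e in exprs:
        print(f"  {e.surface!r} -> {e.resolved} ({e.delta_days:+d} days)")
    if rec.retained:
        print(f"  H = {rec.H_days:+.1f} days "
              f"({'future' if rec.t_ref == 0 else 'past'} reference)")
    else:
        print(f"  dropped: {rec.drop_reason}")

# "tonight" resolves to the posting date anchored at midnight, giving a
# negative raw clock delta on the posting day — a known artifact, so the
# record is dropped rather than miscounted as past reference.
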