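"""Build a synthetic lexicon and inspect its cohort structure.

A cohort is the set of words consistent with the phonemes heard so far; it
shrinks as a word unfolds. The ideal-observer probability of the target is
the reciprocal of the cohort size at each point in time.
"""

import numpy as np

import cohortnet as cn

lex = cn.build_lexicon(
    n_words=50, phoneme_inventory_size=8, length_range=(3, 5),
    neighborhood_density=0.6, seed=0, n_talkers=4,
)
print(f"lexicon: {len(lex)} words over {len(lex.inventory)} phonemes")
print(lex.to_table().head(8).to_string(index=False))

word = lex.words[0]
print(f"\ncohort sizes for word 0 ({len(word)} phonemes):")
for k in range(len(word) + 1):
    size = len(cn.cohort(lex, word, k))
    print(f"  after {k} phonemes heard: {size} candidate(s), "
          f"ideal target probability {1 / size:.3f}")

overlaps = [
    cn.shared_onset_phonemes(a, b)
    for i, a in enumerate(lex.words) for b in lex.words[i + 1:]
]
print("\nshared-onset histogram over word pairs "
      "(0 = unrelated, higher = longer competitors):")
for k in range(max(overlaps) + 1):
    print(f"  {k} shared onset phonemes: {overlaps.count(k)} pairs")
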