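"""Simulate paired V(D)J recombination and inspect junctional diversity.

Builds 200 productive paired B-cell receptors from the packaged synthetic
germline reference and prints segment usage and junction-length summaries.
"""

import collections

import numpy as np

from screpsim import (
    RecombinationSettings,
    load_default_reference,
    simulate_initial_repertoire,
)

reference = load_default_reference()
settings = RecombinationSettings(reference=reference, receptor="B", productive_only=True)
rng = np.random.default_rng(0)

pairs = simulate_initial_repertoire(200, settings, rng)

v_usage = collections.Counter(p.heavy.v_id for p in pairs)
junction_lengths = [len(p.heavy.junction_nt) for p in pairs]

print(f"clones: {len(pairs)}, all productive: "
      f"{all(p.heavy.productive and p.light.productive for p in pairs)}")
print("top heavy V usage:", v_usage.most_common(3))
print(f"heavy junction (CDR3 proxy) length: mean {np.mean(junction_lengths):.1f} nt, "
      f"range {min(junction_lengths)}-{max(junction_lengths)}")
# With uniform usage every V gene is drawn at ~1/12.  The junction spans
# the last 3 V nt through the first 3 J nt: a ~15 nt D core that loses
# 0-3 nt per trimmed end plus 0-6 random nt per junction, so ~24 nt on
# average with wide spread.
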