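"""Sequence-motif detection from attention maps.

The attention map M assigns each position the attention mass it receives
in the final transformer layer, summed over heads and query positions;
maximal runs of positions above mean + 1 sd are reported as motif calls.
"""

import numpy as np

from rnaembed import ModelConfig, attention_map, call_motifs, init_params, tokenize
from rnaembed.seqio import RnaSequence

config = ModelConfig(D=24, n_layers=2, H=4, ffn_dim=96)
params = init_params(config, np.random.default_rng(1))

seq = RnaSequence("demo", "GGGAUCGUUCGAAGCUAGCAAUGGCUAGCAA")
m = attention_map(tokenize(seq, config), params, config)
print(f"attention map (sums to n*H = {len(seq) * config.H}):")
print(np.round(m, 2))

calls = call_motifs(seq, m, min_len=3, threshold_sd=1.0)
if not calls:
    print("no motif call above mean + 1 sd for this untrained model")
for c in calls:
    print(f"motif {c.start}-{c.end}: {c.subsequence} (mean salience {c.mean_salience:.2f})")
# with a trained model, conserved functional elements (e.g. box motifs)
# concentrate attention mass and emerge as calls
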