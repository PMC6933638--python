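"""Small helpers shared by open-set tests and acceptance checks."""

import numpy as np

from mircnn.openset import max_softmax_scores

from conftest import encode_onehot_seqs


def score_seqs(classifier, seqs) -> np.ndarray:
    """Max-softmax scores for raw sequences under a one-hot classifier."""
    X = encode_onehot_seqs(seqs, L=classifier.config.L)
    return np.array([sp.max_prob for sp in max_softmax_scores(classifier, X)])
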