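import numpy as np
import pandas as pd


def null_matrix(n1: int, n2: int, n_probes: int, seed: int) -> tuple:
    """Expression matrix with no group effect, for null-calibration checks."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n1 + n2, n_probes)),
        columns=[f"P{i:04d}" for i in range(n_probes)],
    )
    y = np.array([0] * n1 + [1] * n2, dtype=bool)
    return X, y


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance with half credit for ties."""
    import itertools
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    total, conc = 0, 0.0
    for i, j in itertools.product(np.flatnonzero(y), np.flatnonzero(~y)):
        total += 1
        conc += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
    return conc / total
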