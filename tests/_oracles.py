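"""Independent reference implementations used only as test oracles."""

import numpy as np


def brute_force_silhouette(D, labels):
    """Literal O(n^2) silhouette: explicit loops over the defining formula."""
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = sum(D[i, j] for j in same) / len(same)
        b = np.inf
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(D[i, j] for j in other) / len(other))
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s
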