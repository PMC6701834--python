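"""Small shared test utilities."""

import numpy as np


def match_events(detected: np.ndarray, truth: np.ndarray, tol: int):
    """Greedy matching of detected troughs to ground-truth spike samples.

    Returns (recall, precision). Each truth spike can absorb one detection.
    """
    detected = np.sort(np.asarray(detected))
    truth = np.sort(np.asarray(truth))
    hit = np.zeros(truth.size, dtype=bool)
    fp = 0
    for d in detected:
        k = np.searchsorted(truth, d)
        cand = [c for c in (k - 1, k) if 0 <= c < truth.size and abs(truth[c] - d) <= tol]
        if cand:
            hit[cand[0]] = True
        else:
            fp += 1
    recall = hit.mean() if truth.size else 1.0
    precision = 1.0 - fp / detected.size if detected.size else 1.0
    return float(recall), float(precision)
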