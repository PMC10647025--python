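"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain Python loops and explicit counting, sharing no
code with the library paths they verify.
"""

import numpy as np


def brute_force_threshold(statistics, positive):
    """Exhaustive midpoint search minimizing balanced error by counting."""
    stats = [float(s) for s in statistics]
    pos = [bool(p) for p in positive]
    distinct = sorted(set(stats))
    candidates = [distinct[0] - 1.0]
    for a, b in zip(distinct[:-1], distinct[1:]):
        candidates.append((a + b) / 2.0)
    candidates.append(distinct[-1] + 1.0)

    best_theta, best_err = None, None
    for theta in candidates:
        miss = sum(1 for s, p in zip(stats, pos) if p and s < theta)
        fa = sum(1 for s, p in zip(stats, pos) if not p and s >= theta)
        n_pos = sum(pos)
        n_neg = len(pos) - n_pos
        err = 0.5 * (miss / n_pos + fa / n_neg)
        if best_err is None or err < best_err - 1e-15:
            best_theta, best_err = theta, err
    return best_theta, best_err


def tally_balanced_accuracy(counts):
    """Mean per-class recall by explicit row counting."""
    recalls = []
    for i, row in enumerate(counts):
        total = sum(row)
        recalls.append(row[i] / total)
    return sum(recalls) / len(recalls)


def tally_macro_f1(counts):
    """Unweighted mean one-vs-rest F1 by explicit tallying."""
    k = len(counts)
    scores = []
    for c in range(k):
        tp = counts[c][c]
        fp = sum(counts[r][c] for r in range(k) if r != c)
        fn = sum(counts[c][p] for p in range(k) if p != c)
        if 2 * tp + fp + fn == 0:
            scores.append(0.0)
        else:
            scores.append(2 * tp / (2 * tp + fp + fn))
    return sum(scores) / k


def leave_one_out_loss(X, labels, trainer):
    """Hand-rolled LOO: train on all-but-one, test the held-out sample."""
    X = np.asarray(X)
    labels = np.asarray(labels)
    wrong = 0
    for i in range(labels.size):
        keep = [j for j in range(labels.size) if j != i]
        predictor = trainer(X[keep], labels[keep])
        wrong += int(np.asarray(predictor(X[i:i + 1]))[0] != labels[i])
    return wrong / labels.size
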