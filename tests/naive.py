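"""Independent brute-force reference implementations used as test oracles.

Deliberately written as plain per-placement Python loops, mirroring the
defining formulas directly (dilated sliding dot product, strict-positive
pooling), so they share no code path with the vectorized package.
"""

import numpy as np


def naive_convolve(x, channels, weights, bias, dilation, padding):
    """Per-placement dilated sliding dot product over selected channels."""
    x = np.asarray(x, dtype=float)
    length = weights.shape[1]
    span = (length - 1) * dilation
    if padding:
        pad = span // 2
        x = np.concatenate(
            [np.zeros((x.shape[0], pad)), x, np.zeros((x.shape[0], pad))], axis=1
        )
    n_out = x.shape[1] - span
    out = []
    for t in range(n_out):
        s = bias
        for ci, ch in enumerate(channels):
            for j in range(length):
                s += x[ch, t + j * dilation] * weights[ci, j]
        out.append(s)
    return np.array(out)


def naive_ppv(c):
    return sum(1 for v in c if v > 0) / len(c)


def naive_rocket_features(trials, bank):
    """Per-trial, per-kernel [ppv, max] via the naive convolution."""
    rows = []
    for trial in trials:
        row = []
        for k in bank.kernels:
            c = naive_convolve(trial, k.channels, k.weights, k.bias, k.dilation, k.padding)
            row.extend([naive_ppv(c), max(c)])
        rows.append(row)
    return np.array(rows)


def naive_minirocket_features(trials, fitted, tie_tol=1e-9):
    """Two-pass reference: convolves w and -w explicitly.

    The inverted-kernel feature is ppv of the explicit (-w) convolution
    against bias -b (c_neg + b > 0 <=> c_pos - b < 0), i.e. a second
    convolution rather than the 1 - ppv shortcut.

    Also returns a tie mask flagging features whose convolution output
    comes within ``tie_tol`` of the bias somewhere: there the strict
    threshold amplifies float summation-order differences between the two
    passes, so only tie-free features are exactly comparable.
    """
    rows, ties = [], []
    for trial in trials:
        row, tie_row = [], []
        for ci, combo in enumerate(fitted.combos):
            n_f = int(fitted.features_per_combo[ci])
            if n_f == 0:
                continue
            w = np.tile(fitted.patterns[combo.pattern_id].weights, (len(combo.channels), 1))
            c_pos = naive_convolve(trial, combo.channels, w, 0.0, combo.dilation, combo.padding)
            c_neg = naive_convolve(trial, combo.channels, -w, 0.0, combo.dilation, combo.padding)
            for k in range(n_f):
                b = fitted.biases[ci][k // 2]
                if k % 2 == 0:
                    row.append(naive_ppv(c_pos - b))
                else:
                    row.append(naive_ppv(c_neg + b))
                tie_row.append(bool(np.any(np.abs(c_pos - b) < tie_tol)))
        rows.append(row)
        ties.append(tie_row)
    return np.array(rows), np.array(ties, dtype=bool)


def naive_confusion_metrics(y_true, y_pred, class_list):
    """Dict of per-class counts and macro metrics from explicit counting."""
    per = {}
    for c in class_list:
        tp = fp = fn = 0
        for t, p in zip(y_true, y_pred):
            if t == c and p == c:
                tp += 1
            elif t != c and p == c:
                fp += 1
            elif t == c and p != c:
                fn += 1
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[c] = (tp, fp, fn, prec, rec, f1)
    acc = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    macro_p = sum(v[3] for v in per.values()) / len(class_list)
    macro_r = sum(v[4] for v in per.values()) / len(class_list)
    macro_f = sum(v[5] for v in per.values()) / len(class_list)
    return acc, macro_p, macro_r, macro_f, per
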