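"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive every quantity by direct enumeration (per-pair
AUC, per-candidate threshold scans, exhaustive interval search) so they stay
independent of the vectorized implementations they check.
"""

import itertools
import math

import numpy as np


def pairwise_auc(scores, labels):
    """Mann-Whitney AUC by looping over all (diseased, healthy) pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def confusion_brute(scores, labels, t):
    tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= t)
    fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= t)
    fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s < t)
    tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < t)
    return tp, fp, tn, fn


def se_sp_at(scores, labels, t):
    tp, fp, tn, fn = confusion_brute(scores, labels, t)
    return tp / (tp + fn), tn / (tn + fp)


def scan_threshold(scores, labels, method, alpha=1e-12):
    """Exhaustive scan over distinct observed scores; returns the smallest
    optimal threshold after the method's tie-break."""
    cands = sorted(set(scores))
    n1 = sum(labels)
    n0 = len(labels) - n1

    def key(t):
        se, sp = se_sp_at(scores, labels, t)
        if method == "youden":
            return (se + sp,)
        if method == "maxSe":
            return (se, sp)
        if method == "maxSp":
            return (sp, se)
        if method == "roc01":
            return (-math.hypot(1 - se, 1 - sp),)
        if method == "spEqualSe":
            return (-abs(sp - se),)
        if method == "minPvalue":
            tp, fp, tn, fn = confusion_brute(scores, labels, t)
            calls_p, calls_n = tp + fp, tn + fn
            if calls_p == 0 or calls_n == 0:
                chi2 = 0.0
            else:
                n = n0 + n1
                chi2 = n * (tp * tn - fp * fn) ** 2 / (n1 * n0 * calls_p * calls_n)
            return (chi2,)
        raise ValueError(method)

    best = max(cands, key=lambda t: tuple(key(t)) + (-t,))
    # resolve float fuzz: keep the smallest candidate whose key ties the best
    bk = key(best)
    for t in cands:
        if all(abs(a - b) <= alpha for a, b in zip(key(t), bk)):
            return t
    return best


def ui_counts_brute(scores, labels, lower, upper, intersection):
    tn = fn = fp = tp = 0
    for s, y in zip(scores, labels):
        if not (lower <= s <= upper):
            continue
        if s <= intersection:
            if y == 0:
                tn += 1
            else:
                fn += 1
        else:
            if y == 0:
                fp += 1
            else:
                tp += 1
    return tn, fn, fp, tp


def search_ui_brute(scores, labels, intersection, select=0.55):
    """Exhaustive search over all (lower, upper) candidate pairs; returns
    (lower, upper, counts) or None."""
    uniq = sorted(set(scores))
    best = None
    for lo, up in itertools.product(uniq, uniq):
        if not (lo <= intersection <= up):
            continue
        tn, fn, fp, tp = ui_counts_brute(scores, labels, lo, up, intersection)
        if min(tn, fn, fp, tp) < 1:
            continue
        se = tp / (tp + fn)
        sp = tn / (tn + fp)
        if se > select + 1e-9 or sp > select + 1e-9:
            continue
        cand = (tn + fn + fp + tp, up - lo, -lo, (lo, up, (tn, fn, fp, tp)))
        if best is None or cand[:3] > best[:3]:
            best = cand
    return None if best is None else best[3]


def scan_tgroc(scores, labels, level):
    """Direct scan of the Se(t)/Sp(t) series for the TG-ROC bounds."""
    cands = sorted(set(scores))
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    se_ok = [t for t in cands if sum(s >= t for s in pos) / len(pos) >= level]
    sp_ok = [t for t in cands if sum(s < t for s in neg) / len(neg) >= level]
    if not se_ok or not sp_ok:
        return None
    lower, upper = max(se_ok), min(sp_ok)
    reversed_ = lower > upper
    if reversed_:
        lower, upper = upper, lower
    return lower, upper, reversed_
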