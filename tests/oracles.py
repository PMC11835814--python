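"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written by a different route than the
library code: naive tallies, explicit formulas, grid integration, and
least-squares sums of squares.
"""

import math

import numpy as np
import scipy.stats as st

END = "END"


# -- sequence statistics ----------------------------------------------------

def recount_transitions(label_seqs, branch, include_end=True):
    """Naive successor tally over raw label sequences."""
    counts = {}
    for labels in label_seqs:
        for i, lab in enumerate(labels):
            if lab != branch:
                continue
            if i + 1 < len(labels):
                out = labels[i + 1]
            elif include_end:
                out = END
            else:
                continue
            counts[out] = counts.get(out, 0) + 1
    return counts


def te_tally(labels, base=2.0, include_end=True):
    """Direct per-bout transition-entropy tally."""
    pairs = []
    for i in range(len(labels)):
        if i + 1 < len(labels):
            pairs.append((labels[i], labels[i + 1]))
        elif include_end:
            pairs.append((labels[i], END))
    if not pairs:
        return 0.0
    te = 0.0
    types = {a for a, _ in pairs}
    for a in types:
        succ = [b for x, b in pairs if x == a]
        n_a = len(succ)
        h = 0.0
        for b in set(succ):
            p = succ.count(b) / n_a
            h -= p * math.log(p, base)
        te += h * n_a / len(pairs)
    return te


def greedy_chunk_starts(labels, chunk):
    """All match positions, then leftmost non-overlapping selection."""
    k = len(chunk)
    positions = [i for i in range(len(labels) - k + 1)
                 if list(labels[i:i + k]) == list(chunk)]
    chosen, last_end = [], -1
    for i in positions:
        if i >= last_end:
            chosen.append(i)
            last_end = i + k
    return chosen


def grid_overlap(intervals_a, intervals_b, lo, hi, dx=0.0005):
    """Overlap length of two interval sets by grid integration."""
    x = np.arange(lo, hi, dx)
    in_a = np.zeros(len(x), dtype=bool)
    for a, b in intervals_a:
        in_a |= (x >= a) & (x < b)
    in_b = np.zeros(len(x), dtype=bool)
    for a, b in intervals_b:
        in_b |= (x >= a) & (x < b)
    return float(np.sum(in_a & in_b)) * dx


# -- statistical tests ------------------------------------------------------

def chi2_two_proportions(k1, n1, k2, n2, continuity=True):
    """Explicit 2x2 chi-square with optional Yates correction."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    exp = rows @ cols / obs.sum()
    diff = np.abs(obs - exp)
    if continuity:
        diff = np.maximum(0.0, diff - 0.5)
    stat = float((diff ** 2 / exp).sum())
    return stat, float(st.chi2.sf(stat, 1))


def anova_f(values, groups):
    """scipy's one-way ANOVA as the independent route."""
    levels = sorted(set(groups))
    samples = [np.asarray([v for v, g in zip(values, groups) if g == lev])
               for lev in levels]
    res = st.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)


def tukey_kramer(values, groups):
    """Manual Tukey-Kramer adjusted p per pair via the studentized range."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    samples = {g: values[groups == g] for g in levels}
    k = len(levels)
    df_w = len(values) - k
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / df_w
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            na, nb = len(samples[a]), len(samples[b])
            se = math.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            q = abs(samples[a].mean() - samples[b].mean()) / se
            out[(a, b)] = float(st.studentized_range.sf(q, k, df_w))
    return out


def main_effects_anova(values, factors):
    """Type-II main-effects F via explicit least-squares RSS differences."""
    y = np.asarray(values, dtype=float)
    n = len(y)

    def dummies(vals):
        levels = sorted(set(map(str, vals)))
        cols = []
        for lev in levels[1:]:
            cols.append(np.array([1.0 if str(v) == lev else 0.0 for v in vals]))
        return np.column_stack(cols) if cols else np.empty((n, 0))

    blocks = {name: dummies(vals) for name, vals in factors.items()}

    def rss(names):
        X = np.column_stack([np.ones(n)] + [blocks[m] for m in names]) \
            if names else np.ones((n, 1))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    all_names = list(factors)
    rss_full, p_full = rss(all_names)
    df_resid = n - p_full
    out = {}
    for name in all_names:
        rss_red, _ = rss([m for m in all_names if m != name])
        df_f = blocks[name].shape[1]
        ss = rss_red - rss_full
        if rss_full <= 1e-12:
            f = 0.0 if ss <= 1e-12 else np.inf
            p = 1.0 if ss <= 1e-12 else 0.0
        else:
            f = (ss / df_f) / (rss_full / df_resid)
            p = float(st.f.sf(f, df_f, df_resid))
        out[name] = (float(f), p, df_f, df_resid)
    return out


def paired_t_formula(x, y):
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return float(t), float(2.0 * st.t.sf(abs(t), n - 1))


def pearson_formula(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = float(((x - x.mean()) * (y - y.mean())).sum()
              / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    n = len(x)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, float(2.0 * st.t.sf(abs(t), n - 2))
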