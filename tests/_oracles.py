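"""Independent brute-force reimplementations used as test oracles.

Deliberately naive (dicts and explicit loops, no pandas vectorization) so
they share no code path with the package.
"""

from collections import defaultdict
from itertools import combinations


def rows_from_df(df):
    return [(r.sample_id, int(r.replicate), r.marker, r.taxon_id, int(r.reads))
            for r in df.itertuples()]


def naive_min_reads(rows, threshold):
    totals = defaultdict(int)
    for s, rep, m, t, c in rows:
        totals[(m, t)] += c
    return [row for row in rows if totals[(row[2], row[3])] >= threshold]


def naive_replicate_support(rows, min_support=2):
    rows = [r for r in rows if r[4] > 0]
    reps_per_sample = defaultdict(set)
    for s, rep, m, t, c in rows:
        reps_per_sample[s].add(rep)
    excluded = {s for s, reps in reps_per_sample.items() if len(reps) < min_support}
    rows = [r for r in rows if r[0] not in excluded]
    support = defaultdict(set)
    for s, rep, m, t, c in rows:
        support[(s, t)].add(rep)
    kept = [r for r in rows if len(support[(r[0], r[3])]) >= min_support]
    return kept, excluded


def naive_rra_merge(rows, renormalize=True):
    """Per-replicate RRA (markers pooled) then mean-merge and renormalize.
    Returns {sample: {taxon: rra}}."""
    totals = defaultdict(int)
    for s, rep, m, t, c in rows:
        totals[(s, rep)] += c
    per_rep = defaultdict(dict)
    for s, rep, m, t, c in rows:
        if totals[(s, rep)] > 0 and c > 0:
            per_rep[(s, rep)][t] = per_rep[(s, rep)].get(t, 0) + c / totals[(s, rep)]
    by_sample = defaultdict(list)
    for (s, rep), vec in per_rep.items():
        by_sample[s].append(vec)
    out = {}
    for s, vecs in by_sample.items():
        taxa = sorted({t for v in vecs for t in v})
        merged = {t: sum(v.get(t, 0.0) for v in vecs) / len(vecs) for t in taxa}
        if renormalize:
            z = sum(merged.values())
            merged = {t: x / z for t, x in merged.items()}
        out[s] = merged
    return out


def naive_anthropogenic_percentage(rra_row, scores):
    num = sum(scores[t] * v for t, v in rra_row.items())
    den = sum(rra_row.values())
    return 100.0 * num / den


def naive_bray_curtis(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def naive_permanova_ss(d, labels):
    """(SS_total, SS_within, SS_among, F, R^2) by explicit double loops."""
    n = len(labels)
    ss_total = 0.0
    for i, j in combinations(range(n), 2):
        ss_total += d[i][j] ** 2
    ss_total /= n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_g = 0.0
        for i, j in combinations(idx, 2):
            ss_g += d[i][j] ** 2
        ss_within += ss_g / len(idx)
    ss_among = ss_total - ss_within
    a = len(groups)
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return ss_total, ss_within, ss_among, f, ss_among / ss_total
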