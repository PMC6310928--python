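"""Independent brute-force oracles used to verify the scoring statistics.

Deliberately naive, loop-based implementations kept separate from the
package code paths they check.
"""

from __future__ import annotations

import numpy as np


def ssgsea_oracle(gene_ids, expression, set_genes, alpha):
    """Exhaustive stepwise running-sum ssGSEA for one sample.

    Ranks genes by expression descending (ties by gene id ascending),
    walks every rank position accumulating normalized hit weights
    (N - position + 1)^alpha and uniform miss penalties, and sums the
    running difference.
    """
    order = sorted(range(len(gene_ids)), key=lambda i: (-expression[i], gene_ids[i]))
    n = len(gene_ids)
    in_set = [gene_ids[i] in set_genes for i in order]
    n_hit = sum(in_set)
    assert 0 < n_hit < n
    hit_weights = []
    for pos0, hit in enumerate(in_set):
        position = pos0 + 1
        hit_weights.append(abs(n - position + 1) ** alpha if hit else 0.0)
    total_hit = sum(hit_weights)
    es = 0.0
    cum_hit = 0.0
    cum_miss = 0.0
    for pos0, hit in enumerate(in_set):
        if hit:
            cum_hit += hit_weights[pos0] / total_hit
        else:
            cum_miss += 1.0 / (n - n_hit)
        es += cum_hit - cum_miss
    return es


def gsea_es_oracle(ranked_genes, metric, set_genes, p_weight):
    """Exhaustive enumeration of the weighted KS running sum.

    Returns the signed maximum deviation from zero over all positions.
    """
    n = len(ranked_genes)
    in_set = [g in set_genes for g in ranked_genes]
    n_hit = sum(in_set)
    assert 0 < n_hit < n
    weights = [abs(m) ** p_weight if hit else 0.0 for m, hit in zip(metric, in_set)]
    total = sum(weights)
    if total == 0:
        weights = [1.0 if hit else 0.0 for hit in in_set]
        total = float(n_hit)
    running = 0.0
    best = 0.0
    for pos in range(n):
        if in_set[pos]:
            running += weights[pos] / total
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def km_oracle(times, events):
    """Hand product-limit estimator: S at each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = np.unique(times[events == 1])
    surv = []
    s = 1.0
    for t in event_times:
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / at_risk
        surv.append(s)
    return event_times, np.asarray(surv)


def hub_oracle(genes, weights, min_neighbors, min_weight):
    """Brute-force hub rule: count, per gene, neighbors with w > threshold."""
    hubs = []
    n = len(genes)
    for i in range(n):
        count = 0
        for j in range(n):
            if i != j and weights[i][j] > min_weight:
                count += 1
        if count >= min_neighbors:
            hubs.append(genes[i])
    return hubs
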