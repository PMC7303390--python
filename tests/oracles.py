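"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — explicit loops and textbook
formulas — and shares no code path with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass Pearson correlation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def pearson_p_two_sided(r: float, n: int) -> float:
    """Two-sided p for Pearson r via the t distribution (scipy CDF only)."""
    from scipy.stats import t as tdist

    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return 2 * tdist.sf(abs(t), n - 2)


def fisher_z_matrix(ts: np.ndarray, clip: float) -> np.ndarray:
    """FC oracle: per-pair two-pass Pearson then atanh, zero diagonal."""
    p = ts.shape[1]
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                r = pearson_two_pass(ts[:, i], ts[:, j])
                out[i, j] = math.atanh(max(-clip, min(clip, r)))
    return out


def bh_step_up(p_values, q: float):
    """Benjamini-Hochberg step-up, by the definition.

    Returns (reject flags, adjusted p) as plain lists.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    # largest k with p_(k) <= k/m * q
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p_values[i] <= rank / m * q:
            k_star = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            reject[i] = True
    # adjusted p: min over j >= rank of m/j * p_(j), capped at 1
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m / rank * p_values[i])
        adj_sorted[rank - 1] = running
    adjusted = [0.0] * m
    for rank, i in enumerate(order, start=1):
        adjusted[i] = adj_sorted[rank - 1]
    return reject, adjusted


def sc_tally_hard(endpoint_pairs, lengths, mean_qas, n_parcels: int):
    """SC oracle for hard (0/1) parcel assignments.

    ``endpoint_pairs`` holds 1-based (start_parcel, end_parcel) per
    streamline (0 = outside every parcel).  Returns (NS, ML, QA)
    unnormalized matrices as nested lists.
    """
    ns = [[0.0] * n_parcels for _ in range(n_parcels)]
    ml = [[0.0] * n_parcels for _ in range(n_parcels)]
    qa = [[0.0] * n_parcels for _ in range(n_parcels)]
    for (a, b), length, q in zip(endpoint_pairs, lengths, mean_qas):
        if a == 0 or b == 0 or a == b:
            continue
        i, j = a - 1, b - 1
        for u, v in ((i, j), (j, i)):
            ns[u][v] += 1
            ml[u][v] += length
            qa[u][v] += q
    for i in range(n_parcels):
        for j in range(n_parcels):
            if ns[i][j] > 0:
                ml[i][j] /= ns[i][j]
                qa[i][j] /= ns[i][j]
    return ns, ml, qa


def exhaustive_identification_p(scores: np.ndarray) -> tuple[float, int, int]:
    """Permutation p by enumerating every relabeling of target ids.

    Returns (add-one p over the full enumeration, exceedance count,
    number of relabelings).
    """
    n = scores.shape[0]
    pred_rt = [int(np.argmax(scores[i])) for i in range(n)]
    pred_tr = [int(np.argmax(scores[:, k])) for k in range(n)]
    obs = (np.mean([pred_rt[i] == i for i in range(n)])
           + np.mean([pred_tr[k] == k for k in range(n)])) / 2
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        acc_rt = np.mean([perm[pred_rt[i]] == i for i in range(n)])
        acc_tr = np.mean([pred_tr[k] == perm[k] for k in range(n)])
        if (acc_rt + acc_tr) / 2 >= obs:
            count += 1
        total += 1
    return (1 + count) / (total + 1), count, total
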