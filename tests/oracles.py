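"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented from first principles — ray
casting, all-pairs concordance, textbook product-limit formulas, an
explicitly written Cox partial likelihood — and never calls into the
package code paths it checks.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def ray_cast_inside(px: np.ndarray, py: np.ndarray, rings) -> np.ndarray:
    """Even-odd point-in-polygon by horizontal ray casting, vectorized over
    query points.  ``rings`` is a list of vertex lists (closed or open);
    crossing parity is accumulated over every ring, so holes and disjoint
    loops follow the even-odd rule."""
    px = np.asarray(px, float).ravel()
    py = np.asarray(py, float).ravel()
    inside = np.zeros(px.shape, dtype=bool)
    for ring in rings:
        v = np.asarray(ring, float)
        if np.all(v[0] == v[-1]):
            v = v[:-1]
        x1, y1 = v[:, 0], v[:, 1]
        x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
        for xa, ya, xb, yb in zip(x1, y1, x2, y2):
            crosses = (ya > py) != (yb > py)
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = xa + (py - ya) * (xb - xa) / (yb - ya)
            inside ^= crosses & (px < xint)
    return inside


def brute_force_image_score(coords, probs, rings, patch_size, tau,
                            boundary="at_least"):
    """Per-patch loop: centre-pixel-centre ray cast, then threshold count.
    Returns (n_total, n_pos)."""
    n_total = n_pos = 0
    for (x, y), p in zip(coords, probs):
        cx = x + patch_size // 2 + 0.5
        cy = y + patch_size // 2 + 0.5
        if ray_cast_inside(np.array([cx]), np.array([cy]), rings)[0]:
            n_total += 1
            pos = p >= tau if boundary == "at_least" else p > tau
            n_pos += int(pos)
    return n_total, n_pos


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def concordance_auc(scores, died) -> float:
    """All-pairs probability that a decedent scores below a survivor, ties
    counted half — the rank definition of AUC for the low-score-is-positive
    orientation."""
    scores = np.asarray(scores, float)
    died = np.asarray(died, int)
    pos = scores[died == 1]
    neg = scores[died == 0]
    total = len(pos) * len(neg)
    conc = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / total


def exhaustive_youden(scores, died):
    """Max Youden's J over midpoint candidate thresholds (plus sentinels),
    ties toward the smaller threshold.  Returns (threshold, J)."""
    scores = np.asarray(scores, float)
    died = np.asarray(died, int)
    uniq = np.unique(scores)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best_t, best_j = None, -np.inf
    for t in cands:
        pred = scores < t
        sens = (pred & (died == 1)).sum() / (died == 1).sum()
        spec = (~pred & (died == 0)).sum() / (died == 0).sum()
        j = sens + spec - 1
        if j > best_j:  # strict: first (smallest) max wins
            best_t, best_j = t, j
    return best_t, best_j


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def product_limit(time, event):
    """Textbook Kaplan-Meier: returns (event_times, S) with
    S_j = prod_{t_i <= t_j} (1 - d_i / n_i)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    uniq = np.unique(time[event == 1])
    surv = []
    s = 1.0
    for t in uniq:
        n_at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return uniq, np.array(surv)


def logrank_hand(time_a, event_a, time_b, event_b):
    """(O - E)^2 / V summed over distinct event times, hypergeometric
    expectation and variance."""
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    O = E = V = 0.0
    for t in np.unique(t_all[e_all == 1]):
        n1 = (ta >= t).sum()
        n = (t_all >= t).sum()
        d = ((t_all == t) & (e_all == 1)).sum()
        d1 = ((ta == t) & (ea == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def cox_partial_loglik(beta, time, event, x):
    """Explicit no-ties Cox partial log-likelihood for a single covariate:
    sum over events i of [beta*x_i - log(sum_{t_j >= t_i} exp(beta*x_j))]."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


def cox_grid_mle(time, event, x, lo=-5.0, hi=5.0, tol=1e-6):
    """Golden-section maximization of the explicit partial likelihood."""
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc = cox_partial_loglik(c, time, event, x)
    fd = cox_partial_loglik(d, time, event, x)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = cox_partial_loglik(c, time, event, x)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = cox_partial_loglik(d, time, event, x)
    return (a + b) / 2


# ---------------------------------------------------------------------------
# ranks
# ---------------------------------------------------------------------------


def midranks(v) -> np.ndarray:
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), float)
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_via_midranks(a, b) -> float:
    ra, rb = midranks(a), midranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def kruskal_hand(groups):
    """Tie-corrected Kruskal-Wallis H from rank sums."""
    allv = np.concatenate(groups)
    n = len(allv)
    ranks = midranks(allv)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(allv, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction
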