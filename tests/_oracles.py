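"""Independent straight-line oracles used by the test suite.

Everything here is written as literal scalar loops over the defining
equations — no code is shared with the package's implementation — so the
tests compare two independently derived computations.
"""

import math

BASES = "ACGU"


def sig(z):
    return 1.0 / (1.0 + math.exp(-z))


def th(z):
    return (math.exp(2 * z) - 1.0) / (math.exp(2 * z) + 1.0)


def onehot_matrix(residues, margin, padded_length):
    """Zero-padded one-hot as a list of 4-lists."""
    rows = [[0.0] * 4 for _ in range(padded_length)]
    for j, b in enumerate(residues):
        if b in BASES:
            rows[margin + j][BASES.index(b)] = 1.0
    return rows


def scalar_conv(rows, weights):
    """Rectified scores of one filter (list of [4]-rows) over padded rows."""
    m = len(weights)
    out = []
    for p in range(len(rows) - m + 1):
        acc = 0.0
        for i in range(m):
            for c in range(4):
                acc += weights[i][c] * rows[p + i][c]
        out.append(acc if acc > 0 else 0.0)
    return out


def scalar_wta(scores):
    """Double the first maximum, then square everything."""
    best = 0
    for i, s in enumerate(scores):
        if s > scores[best]:
            best = i
    doubled = list(scores)
    doubled[best] *= 2.0
    return [v * v for v in doubled]


def scalar_lstm_step(x, h_prev, c_prev, p):
    """One step of the gate equations with explicit loops.

    ``p`` is a dict with keys W_xi, W_hi, b_i (and f, g, o variants);
    matrices are lists of rows: W_x* is (input_dim x n), W_h* is (n x n).
    """
    n = len(p["b_i"])

    def affine(gate):
        out = []
        for j in range(n):
            acc = p["b_" + gate][j]
            for a in range(len(x)):
                acc += p["W_x" + gate][a][j] * x[a]
            for a in range(n):
                acc += p["W_h" + gate][a][j] * h_prev[a]
            out.append(acc)
        return out

    i = [sig(v) for v in affine("i")]
    f = [sig(v) for v in affine("f")]
    g = [th(v) for v in affine("g")]
    o = [sig(v) for v in affine("o")]
    c = [f[j] * c_prev[j] + i[j] * g[j] for j in range(n)]
    h = [o[j] * th(c[j]) for j in range(n)]
    return h, c


def scalar_forward(residues, conv_weights, fwd_gates, bwd_gates, hidden):
    """Full forward pass: conv bank -> WTA -> tracks -> BLSTM -> profile.

    ``conv_weights``: list of (m x 4) nested lists.  ``fwd_gates`` and
    ``bwd_gates``: per-gate dicts as in :func:`scalar_lstm_step`.  Returns
    (profile list over real bases, score).
    """
    m_max = max(len(w) for w in conv_weights)
    margin = m_max - 1
    L = len(residues) + 2 * margin
    rows = onehot_matrix(residues, margin, L)

    tracks = []
    for w in conv_weights:
        enhanced = scalar_wta(scalar_conv(rows, w))
        track = [[0.0] * 4 for _ in range(L)]
        for p_i, e in enumerate(enhanced):
            for c in range(4):
                track[p_i][c] = rows[p_i][c] * e
        tracks.append(track)

    xs = []
    for t in range(L):
        x = []
        for track in tracks:
            x.extend(track[t])
        x.extend(rows[t])
        xs.append(x)

    # the recurrence skips padded time steps (state carry), so running it
    # over the real region only is equivalent
    real = list(range(margin, margin + len(residues)))
    h = [0.0] * hidden
    c = [0.0] * hidden
    h_f = {}
    for t in real:
        h, c = scalar_lstm_step(xs[t], h, c, fwd_gates)
        h_f[t] = h
    h = [0.0] * hidden
    c = [0.0] * hidden
    h_b = {}
    for t in reversed(real):
        h, c = scalar_lstm_step(xs[t], h, c, bwd_gates)
        h_b[t] = h

    profile = []
    for t in real:
        profile.append(sum(h_f[t]) + sum(h_b[t]))
    return profile, sig(sum(profile))


def gate_dicts(params):
    """Convert a packed LSTMGateParams into the oracle's per-gate dict."""
    out = {}
    for gate in "ifgo":
        out["W_x" + gate] = [list(r) for r in getattr(params, "W_x" + gate)]
        out["W_h" + gate] = [list(r) for r in getattr(params, "W_h" + gate)]
        out["b_" + gate] = list(getattr(params, "b_" + gate))
    return out


def brute_auroc(scores, labels):
    """Pair-count AUROC: fraction of (pos, neg) pairs ranked correctly,
    ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_call_sites(profile, window, threshold):
    """Enumerate qualifying windows; merge overlapping ones by computing
    connected components of the pairwise-overlap graph (union-find), each
    component spanning [min start, max end].  Windows that merely touch do
    not overlap and stay separate."""
    qualifying = []
    for s in range(len(profile) - window + 1):
        if sum(profile[s : s + window]) / window > threshold:
            qualifying.append((s, s + window))
    n = len(qualifying)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            (lo1, hi1), (lo2, hi2) = qualifying[i], qualifying[j]
            if lo1 < hi2 and lo2 < hi1:
                parent[find(i)] = find(j)
    components = {}
    for i in range(n):
        components.setdefault(find(i), []).append(qualifying[i])
    sites = []
    for group in components.values():
        sites.append((min(lo for lo, _ in group), max(hi for _, hi in group)))
    return sorted(sites)


def legal_background_starts(gene, peaks, width):
    """Every start position in ``gene`` where a width-``width`` interval
    overlaps no peak."""
    out = []
    for s in range(gene.start, gene.end - width + 1):
        if all(s + width <= p.start or p.end <= s for p in peaks):
            out.append(s)
    return out


def brute_track_assignment(rows, enhanced, m, rule):
    """Per-position enhanced-value assignment by explicit enumeration."""
    L = len(rows)
    n_place = len(enhanced)
    assigned = [0.0] * L
    for j in range(L):
        if rule == "start":
            if j < n_place:
                assigned[j] = enhanced[j]
        else:  # max over covering placements
            vals = [
                enhanced[p]
                for p in range(n_place)
                if p <= j <= p + m - 1
            ]
            assigned[j] = max(vals) if vals else 0.0
    return [[rows[j][c] * assigned[j] for c in range(4)] for j in range(L)]
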