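"""Independent brute-force reference implementations.

Everything here is written as plain nested loops or explicit projection
algebra, deliberately sharing no code path with the package, so agreement
is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import numpy as np


def sampen_counts_brute(x: np.ndarray, M: int, r: float) -> tuple[int, int]:
    """O(N²) template-pair counting for sample entropy."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - M  # templates that still have an (M+1)-th point
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(M))
            if d_m <= r:
                b += 1
                if max(d_m, abs(x[i + M] - x[j + M])) <= r:
                    a += 1
    return a, b


def sampen_brute(x: np.ndarray, M: int, r: float) -> float:
    a, b = sampen_counts_brute(x, M, r)
    if b == 0:
        raise ValueError("no matches")
    return float("inf") if a == 0 else -np.log(a / b)


def ami_brute(bins: np.ndarray, n_bins: int, max_lag: int) -> np.ndarray:
    """Mutual information per lag from explicit pair iteration over given
    bin assignments (nats)."""
    n = len(bins)
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        joint: dict[tuple[int, int], int] = {}
        px: dict[int, int] = {}
        py: dict[int, int] = {}
        total = 0
        for t in range(n - lag):
            key = (int(bins[t]), int(bins[t + lag]))
            joint[key] = joint.get(key, 0) + 1
            px[key[0]] = px.get(key[0], 0) + 1
            py[key[1]] = py.get(key[1], 0) + 1
            total += 1
        mi = 0.0
        for (i, j), c in joint.items():
            pij = c / total
            mi += pij * np.log(pij / ((px[i] / total) * (py[j] / total)))
        out[lag] = mi
    return out


def embed_brute(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_vec = len(x) - (m - 1) * tau
    return np.array([[x[t + k * tau] for k in range(m)] for t in range(n_vec)])


def fnn_brute(
    x: np.ndarray, tau: int, m_max: int, rtol: float = 15.0, atol: float = 2.0
) -> np.ndarray:
    """False-nearest-neighbor fractions by exhaustive neighbor search."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r_a = float(np.std(x))
    out = np.empty(m_max)
    for m in range(1, m_max + 1):
        n_vec = n - m * tau
        emb = embed_brute(x, m, tau)[:n_vec]
        n_false = 0
        for i in range(n_vec):
            best_j, best_d = -1, np.inf
            for j in range(n_vec):
                if j == i:
                    continue
                d = np.sqrt(np.sum((emb[i] - emb[j]) ** 2))
                if 0 < d < best_d:
                    best_d, best_j = d, j
            if best_j < 0:
                continue
            e = abs(x[i + m * tau] - x[best_j + m * tau])
            if e / best_d > rtol or np.sqrt(best_d**2 + e**2) / r_a > atol:
                n_false += 1
        out[m - 1] = n_false / n_vec
    return out


def rosenstein_curve_brute(
    x: np.ndarray, m: int, tau: int, n_steps: int, theiler: int
) -> np.ndarray:
    """Mean log2 divergence curve by exhaustive nearest-neighbor search."""
    emb = embed_brute(np.asarray(x, dtype=float), m, tau)
    n = len(emb)
    nn = np.full(n, -1)
    for i in range(n):
        best_j, best_d = -1, np.inf
        for j in range(n):
            if abs(i - j) <= theiler:
                continue
            d = np.sqrt(np.sum((emb[i] - emb[j]) ** 2))
            if 0 < d < best_d:
                best_d, best_j = d, j
        nn[i] = best_j
    curve = np.full(n_steps + 1, np.nan)
    for step in range(n_steps + 1):
        logs = []
        for i in range(n):
            j = nn[i]
            if j < 0 or i + step >= n or j + step >= n:
                continue
            d = np.sqrt(np.sum((emb[i + step] - emb[j + step]) ** 2))
            if d > 0:
                logs.append(np.log2(d))
        if logs:
            curve[step] = np.mean(logs)
    return curve


def anova_projection_oracle(y: np.ndarray) -> dict[str, float]:
    """Mixed 2×2×2 ANOVA F statistics via orthonormal projection algebra.

    ``y`` has shape (2, n, 2, 2) = (group, subject, condition, visit).
    Each effect's SS is the squared norm of the data's projection onto the
    Kronecker-product contrast basis of that effect — an entirely different
    route from mean-difference formulas.
    """
    two, n = y.shape[0], y.shape[1]
    assert two == 2
    vec = y.reshape(-1)  # index order: g, s, c, v

    mean_g = np.ones(2) / np.sqrt(2)
    con_g = np.array([1.0, -1.0]) / np.sqrt(2)
    mean_s = np.ones(n) / np.sqrt(n)
    # orthonormal basis of subject contrasts (within one group)
    q, _ = np.linalg.qr(np.eye(n) - np.ones((n, n)) / n)
    con_s = q[:, : n - 1]

    def kron(*vs):
        out = vs[0]
        for v in vs[1:]:
            out = np.kron(out, v)
        return out

    def ss(columns):
        return float(sum((col @ vec) ** 2 for col in columns))

    c2 = con_g  # reuse the same 2-level contrast for condition and visit
    m2 = mean_g

    effects = {
        "group": [kron(con_g, mean_s, m2, m2)],
        "condition": [kron(mean_g, mean_s, c2, m2)],
        "visit": [kron(mean_g, mean_s, m2, c2)],
        "group x condition": [kron(con_g, mean_s, c2, m2)],
        "group x visit": [kron(con_g, mean_s, m2, c2)],
        "condition x visit": [kron(mean_g, mean_s, c2, c2)],
        "group x condition x visit": [kron(con_g, mean_s, c2, c2)],
    }
    # error strata: subjects within groups, and their interactions
    subj_cols = [kron(g_ind, con_s[:, k], m2, m2) for k in range(n - 1) for g_ind in (np.array([1.0, 0.0]), np.array([0.0, 1.0]))]
    subj_c = [kron(g_ind, con_s[:, k], c2, m2) for k in range(n - 1) for g_ind in (np.array([1.0, 0.0]), np.array([0.0, 1.0]))]
    subj_v = [kron(g_ind, con_s[:, k], m2, c2) for k in range(n - 1) for g_ind in (np.array([1.0, 0.0]), np.array([0.0, 1.0]))]
    subj_cv = [kron(g_ind, con_s[:, k], c2, c2) for k in range(n - 1) for g_ind in (np.array([1.0, 0.0]), np.array([0.0, 1.0]))]

    errors = {
        "group": subj_cols,
        "condition": subj_c,
        "group x condition": subj_c,
        "visit": subj_v,
        "group x visit": subj_v,
        "condition x visit": subj_cv,
        "group x condition x visit": subj_cv,
    }
    df_err = 2 * (n - 1)
    out = {}
    for name, cols in effects.items():
        ms_eff = ss(cols)
        ms_err = ss(errors[name]) / df_err
        out[name] = ms_eff / ms_err
    return out


def bh_stepup_brute(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg decisions from the step-up definition: reject all
    p ≤ p_(k*) where k* is the largest k with p_(k) ≤ k·alpha/m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    if k_star:
        reject[order[:k_star]] = True
    return reject


def icc_oneway_brute(v1: np.ndarray, v2: np.ndarray) -> float:
    """ICC(1,1) via explicit one-way ANOVA sums of squares over the long table."""
    data = np.column_stack([v1, v2]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_between = k * sum((data[i].mean() - grand) ** 2 for i in range(n))
    ss_within = sum((data[i, j] - data[i].mean()) ** 2 for i in range(n) for j in range(k))
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)
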