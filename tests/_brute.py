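"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive: explicit loops over pixel pairs and
matrix entries, no shared code with the package implementation.
"""

import numpy as np

UNIT_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm_counts(patch, d, theta, G, symmetric=True):
    """Pair counts by exhaustive enumeration of every pixel coordinate."""
    patch = np.asarray(patch)
    rows, cols = patch.shape
    ur, uc = UNIT_OFFSETS[theta]
    dr, dc = ur * d, uc * d
    counts = np.zeros((G, G))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[patch[r, c], patch[r2, c2]] += 1
                if symmetric:
                    counts[patch[r2, c2], patch[r, c]] += 1
    return counts


def brute_glcm(patch, d, theta, G, symmetric=True):
    counts = brute_glcm_counts(patch, d, theta, G, symmetric)
    total = counts.sum()
    if total == 0:
        raise ValueError("no pixel pair at this offset")
    return counts / total


def _ent(values):
    h = 0.0
    for v in values:
        if v > 0:
            h -= v * np.log(v)
    return h


def brute_features(P):
    """TF1..TF20 by naive entry-by-entry loops over a normalized GLCM."""
    G = P.shape[0]
    px = [sum(P[i][j] for j in range(G)) for i in range(G)]
    py = [sum(P[i][j] for i in range(G)) for j in range(G)]
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(G))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(G))
    p_plus = [0.0] * (2 * G - 1)
    p_diff = [0.0] * G
    for i in range(G):
        for j in range(G):
            p_plus[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    f = {}
    f["TF1"] = sum(i * j * P[i][j] for i in range(G) for j in range(G))
    f["TF2"] = sum((i - j) ** 2 * P[i][j] for i in range(G) for j in range(G))
    sd = np.sqrt(var_x * var_y)
    f["TF3"] = (f["TF1"] - mu_x * mu_y) / sd if sd > 1e-12 else 1.0
    f["TF4"] = sum((i + j - mu_x - mu_y) ** 4 * P[i][j]
                   for i in range(G) for j in range(G))
    f["TF5"] = sum((i + j - mu_x - mu_y) ** 3 * P[i][j]
                   for i in range(G) for j in range(G))
    f["TF6"] = sum(abs(i - j) * P[i][j] for i in range(G) for j in range(G))
    f["TF7"] = sum(P[i][j] ** 2 for i in range(G) for j in range(G))
    f["TF8"] = _ent(P.ravel())
    f["TF9"] = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    f["TF10"] = max(P.ravel())
    f["TF11"] = sum((i - mu_x) ** 2 * P[i][j] for i in range(G) for j in range(G))
    f["TF12"] = sum(k * p_plus[k] for k in range(2 * G - 1))
    f["TF13"] = _ent(p_plus)
    f["TF14"] = sum((k - f["TF12"]) ** 2 * p_plus[k] for k in range(2 * G - 1))
    mu_d = sum(k * p_diff[k] for k in range(G))
    f["TF15"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(G))
    f["TF16"] = _ent(p_diff)
    hx, hy, hxy = _ent(px), _ent(py), f["TF8"]
    hxy1 = 0.0
    hxy2 = 0.0
    for i in range(G):
        for j in range(G):
            q = px[i] * py[j]
            if q > 0:
                if P[i][j] > 0:
                    hxy1 -= P[i][j] * np.log(q)
                hxy2 -= q * np.log(q)
    hmax = max(hx, hy)
    f["TF17"] = (hxy - hxy1) / hmax if hmax > 1e-12 else 0.0
    f["TF18"] = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    f["TF19"] = sum(P[i][j] / (1 + abs(i - j) / G) for i in range(G) for j in range(G))
    f["TF20"] = sum(P[i][j] / (1 + (i - j) ** 2 / G**2)
                    for i in range(G) for j in range(G))
    return np.array([f[f"TF{k}"] for k in range(1, 21)])


def naive_mutual_information(x_codes, y_codes):
    """Plug-in MI from an explicitly built contingency table."""
    xs = sorted(set(x_codes))
    ys = sorted(set(y_codes))
    n = len(x_codes)
    mi = 0.0
    for xv in xs:
        for yv in ys:
            pxy = sum(1 for a, b in zip(x_codes, y_codes) if a == xv and b == yv) / n
            px = sum(1 for a in x_codes if a == xv) / n
            py = sum(1 for b in y_codes if b == yv) / n
            if pxy > 0:
                mi += pxy * np.log(pxy / (px * py))
    return mi
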