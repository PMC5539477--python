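"""Independent brute-force reference implementations used only by tests.

Each function follows the defining formula of its statistic as literally as
possible (explicit loops, O(N^2) enumeration), with no code shared with the
package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def time_domain_oracle(rr_ms) -> dict:
    rr = list(map(float, rr_ms))
    n = len(rr)
    mean = sum(rr) / n
    sdrr = math.sqrt(sum((x - mean) ** 2 for x in rr) / (n - 1))
    hr = [60000.0 / x for x in rr]
    mhr = sum(hr) / n
    sdhr = math.sqrt(sum((h - mhr) ** 2 for h in hr) / (n - 1))
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    nn50 = sum(1 for d in diffs if abs(d) > 50.0)
    return {
        "mRR": mean, "SDRR": sdrr, "mHR": mhr, "SDHR": sdhr,
        "RMSSD": rmssd, "NN50": float(nn50), "pNN50": 100.0 * nn50 / n,
    }


def apen_oracle(x, m: int, r: float) -> float:
    """Approximate entropy by direct template counting (self-matches in)."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            count = 0
            for b in templates:
                if max(abs(u - v) for u, v in zip(a, b)) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m: int, r: float) -> float | None:
    """Sample entropy by direct pair counting (self-matches excluded).

    Returns None when no length-(m+1) matches exist."""
    x = list(map(float, x))
    n = len(x)

    def count(mm: int) -> int:
        templates = [x[i:i + mm] for i in range(n - m)]
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if max(abs(u - v) for u, v in
                       zip(templates[i], templates[j])) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return None
    return -math.log(a / b)


def correlation_sum_oracle(x, r: float, m: int, delay: int = 1) -> float:
    """C(r) by explicit pairwise Euclidean counting in delay embedding."""
    x = list(map(float, x))
    pts = [x[i:i + (m - 1) * delay + 1:delay]
           for i in range(len(x) - (m - 1) * delay)]
    npts = len(pts)
    count = 0
    for i in range(npts):
        for j in range(i + 1, npts):
            d = math.sqrt(sum((u - v) ** 2 for u, v in zip(pts[i], pts[j])))
            if d < r:
                count += 1
    return 2.0 * count / (npts * (npts - 1))


def rqa_oracle(x, m: int, delay: int, r: float, lmin: int) -> dict:
    """All five recurrence statistics by explicit matrix enumeration."""
    x = list(map(float, x))
    pts = [x[i:i + (m - 1) * delay + 1:delay]
           for i in range(len(x) - (m - 1) * delay)]
    npts = len(pts)
    rec = [[(math.sqrt(sum((u - v) ** 2 for u, v in zip(pts[i], pts[j]))) <= r
             and i != j)
            for j in range(npts)] for i in range(npts)]
    n_rec = sum(sum(row) for row in rec)
    total = npts * (npts - 1)
    out = {"REC": 100.0 * n_rec / total, "Lmean": 0.0, "Lmax": 0.0,
           "DET": 0.0, "ShanEn": 0.0}
    if n_rec == 0:
        return out
    lengths = []
    for k in range(1, npts):
        for diag in ([rec[i][i + k] for i in range(npts - k)],
                     [rec[i + k][i] for i in range(npts - k)]):
            run = 0
            for v in diag:
                if v:
                    run += 1
                elif run:
                    lengths.append(run)
                    run = 0
            if run:
                lengths.append(run)
    lines = [l for l in lengths if l >= lmin]
    if not lines:
        return out
    out["Lmean"] = sum(lines) / len(lines)
    out["Lmax"] = float(max(lines))
    out["DET"] = 100.0 * sum(lines) / n_rec
    probs = {}
    for l in lines:
        probs[l] = probs.get(l, 0) + 1
    tot = sum(probs.values())
    out["ShanEn"] = -sum((c / tot) * math.log(c / tot) for c in probs.values())
    return out


def anova_2x2_oracle(y, a_labels, b_labels) -> dict:
    """Textbook balanced two-way ANOVA sums of squares, computed longhand."""
    y = np.asarray(y, dtype=float)
    a_labels = np.asarray(a_labels)
    b_labels = np.asarray(b_labels)
    a_levels = sorted(set(a_labels))
    b_levels = sorted(set(b_labels))
    grand = y.mean()
    n_cell = len(y) // 4
    ss_a = sum(
        (y[a_labels == a].mean() - grand) ** 2 * (y[a_labels == a].size)
        for a in a_levels
    )
    ss_b = sum(
        (y[b_labels == b].mean() - grand) ** 2 * (y[b_labels == b].size)
        for b in b_levels
    )
    ss_cells = 0.0
    ss_err = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = y[(a_labels == a) & (b_labels == b)]
            ss_cells += n_cell * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_err = len(y) - 4
    ms_err = ss_err / df_err
    return {
        "ss_a": ss_a, "ss_b": ss_b, "ss_ab": ss_ab, "ss_err": ss_err,
        "F_a": ss_a / ms_err, "F_b": ss_b / ms_err, "F_ab": ss_ab / ms_err,
        "df_err": df_err,
    }


def ols_normal_equations_oracle(X, y):
    """beta-hat = (X'X)^-1 X'Y with an explicit inverse."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.inv(X.T @ X) @ X.T @ y
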