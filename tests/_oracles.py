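"""Independent reference implementations used only to check the package.

These deliberately re-derive results by brute force (scalar DP, explicit
alignment enumeration, closed-form statistics) so they share no code with
the implementation under test.
"""

from __future__ import annotations

import itertools
import math

MATCH, MISMATCH, GO, GE = 2, -4, -6, -1
NEG = float("-inf")


def scalar_semiglobal_score(read: str, ref: str) -> float:
    """Plain triple-matrix affine-gap DP, scalar loops, free reference flanks.

    Gap of length L costs GO + L * GE.
    """
    m, n = len(read), len(ref)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = 0.0
    for i in range(1, m + 1):
        for j in range(n + 1):
            F[i][j] = max(H[i - 1][j] + GO + GE, F[i - 1][j] + GE)
            best = F[i][j]
            if j > 0:
                E[i][j] = max(H[i][j - 1] + GO + GE, E[i][j - 1] + GE)
                sub = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
                best = max(best, E[i][j], H[i - 1][j - 1] + sub)
            H[i][j] = best
    return max(H[m])


def enumerate_global_score(read: str, ref: str) -> float:
    """Exhaustive enumeration of every global alignment (tiny inputs only)."""
    best = NEG

    def rec(i: int, j: int, score: float, last: str | None) -> None:
        nonlocal best
        if i == len(read) and j == len(ref):
            best = max(best, score)
            return
        if i < len(read) and j < len(ref):
            sub = MATCH if read[i] == ref[j] else MISMATCH
            rec(i + 1, j + 1, score + sub, "M")
        if i < len(read):
            rec(i + 1, j, score + (GE if last == "I" else GO + GE), "I")
        if j < len(ref):
            rec(i, j + 1, score + (GE if last == "D" else GO + GE), "D")

    rec(0, 0, 0.0, None)
    return best


def enumerate_semiglobal_score(read: str, ref: str) -> float:
    """Free reference flanks by trying every reference window."""
    n = len(ref)
    return max(
        enumerate_global_score(read, ref[s:e])
        for s in range(n + 1)
        for e in range(s, n + 1)
    )


def deletion_placements(ref: str, read: str, length: int) -> list[int]:
    """All start positions q where deleting `length` bases of ref yields read."""
    return [
        q
        for q in range(len(ref) - length + 1)
        if ref[:q] + ref[q + length :] == read
    ]


def insertion_placements(ref: str, read: str, length: int) -> list[tuple[int, str]]:
    """All (point, bases) where inserting into ref yields read."""
    out = []
    for q in range(len(ref) + 1):
        bases = read[q : q + length]
        if read[:q] == ref[:q] and read[q + length :] == ref[q:]:
            out.append((q, bases))
    return out


def paired_t_pvalue(a, b) -> tuple[float, float]:
    """Closed-form paired t via the t survival function (no scipy.ttest)."""
    from scipy.stats import t as tdist

    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    tstat = mean / math.sqrt(var / n)
    p = 2 * tdist.sf(abs(tstat), n - 1)
    return tstat, p


def anova_f(groups: list[list[float]]) -> float:
    """Hand-computed one-way ANOVA F statistic."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def pearson_r(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)
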