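"""Group-comparison statistics.

The battery used throughout the pipeline:

- Kruskal-Wallis omnibus test with tie correction (midranks, chi-square
  reference with k-1 df);
- Steel-Dwass all-pairs nonparametric comparisons: each pair is ranked on its
  own pooled sample, the standardized rank-sum statistic z is computed with
  tie-corrected variance, and sqrt(2)|z| is referred to the studentized range
  distribution with k groups and infinite df;
- MANOVA with Roy's largest root (largest eigenvalue of E^-1 H) and the
  upper-bound F approximation F = theta * df2 / df1 with
  df1 = r = max(p, k-1) and df2 = N - k - r + (k - 1);
- Tukey-Kramer HSD with the unequal-n standard error and studentized range
  df = N - k;
- compact letter displays (groups sharing a letter are not significantly
  different), via the insert-and-absorb algorithm.

Kruskal-Wallis and Tukey-Kramer are computed from first principles here so
they can be cross-checked against independent library implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats


@dataclass
class PairComparison:
    group_a: str
    group_b: str
    statistic: float       # z for Steel-Dwass, q for Tukey-Kramer
    p_value: float
    significant: bool
    note: str = ""


@dataclass
class PairwiseReport:
    method: str
    alpha: float
    pairs: list[PairComparison]
    letters: dict[str, str] = field(default_factory=dict)

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(p.group_a, p.group_b) for p in self.pairs if p.significant]

    def summary(self) -> str:
        lines = [f"{self.method} (alpha={self.alpha})"]
        for p in self.pairs:
            mark = "*" if p.significant else " "
            lines.append(f"  {p.group_a} vs {p.group_b}: stat={p.statistic:.3f} "
                         f"p={p.p_value:.4g} {mark}{(' ' + p.note) if p.note else ''}")
        lines.append("  letters: " + ", ".join(f"{g}:{s}" for g, s in self.letters.items()))
        return "\n".join(lines)


def _split_groups(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    out = {}
    for g in dict.fromkeys(groups.tolist()):  # preserve first-appearance order
        out[str(g)] = values[groups == g]
    return out


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; returns (H, df, p)."""
    by = _split_groups(values, groups)
    k = len(by)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(list(by.values()))
    N = pooled.size
    if N < 3:
        raise ValueError("need at least 3 observations")
    ranks = stats.rankdata(pooled)
    H = 0.0
    i = 0
    for vals in by.values():
        r = ranks[i:i + vals.size]
        H += r.sum() ** 2 / vals.size
        i += vals.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts)
    denom = 1.0 - tie_term / (N ** 3 - N)
    if denom <= 0:  # all values identical
        return 0.0, k - 1, 1.0
    H /= denom
    return float(H), k - 1, float(stats.chi2.sf(H, k - 1))


def _pair_z(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized rank-sum statistic with tie-corrected variance."""
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size
    N = n + m
    ranks = stats.rankdata(pooled)
    W = ranks[:n].sum()
    EW = n * (N + 1) / 2.0
    var = n * m / (N * (N - 1.0)) * (np.sum(ranks ** 2) - N * (N + 1.0) ** 2 / 4.0)
    if var <= 0:
        return 0.0
    return float((W - EW) / np.sqrt(var))


def steel_dwass(values, groups, alpha: float = 0.05) -> PairwiseReport:
    """All-pairs Steel-Dwass comparisons with studentized-range reference."""
    by = _split_groups(values, groups)
    k = len(by)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pairs = []
    for ga, gb in combinations(by, 2):
        a, b = by[ga], by[gb]
        if a.size + b.size < 2 or a.size == 0 or b.size == 0:
            pairs.append(PairComparison(ga, gb, np.nan, np.nan, False,
                                        note="undefined (too few observations)"))
            continue
        z = _pair_z(a, b)
        p = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(z), k, np.inf))
        pairs.append(PairComparison(ga, gb, z, p, p < alpha))
    letters = letter_display(list(by), [(p.group_a, p.group_b)
                                        for p in pairs if p.significant])
    return PairwiseReport("Steel-Dwass", alpha, pairs, letters)


def tukey_kramer(values, groups, alpha: float = 0.05) -> PairwiseReport:
    """Tukey-Kramer HSD with unequal-n standard errors."""
    by = _split_groups(values, groups)
    k = len(by)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = {g: v.size for g, v in by.items()}
    if min(ns.values()) < 2:
        raise ValueError("each group needs at least 2 observations")
    N = sum(ns.values())
    means = {g: v.mean() for g, v in by.items()}
    sse = sum(float(((v - means[g]) ** 2).sum()) for g, v in by.items())
    df = N - k
    mse = sse / df
    pairs = []
    for ga, gb in combinations(by, 2):
        if mse <= 0:
            note = "zero within-group variance"
            diff = abs(means[ga] - means[gb])
            pairs.append(PairComparison(ga, gb, np.inf if diff > 0 else 0.0,
                                        0.0 if diff > 0 else 1.0, diff > 0, note=note))
            continue
        se = np.sqrt(mse / 2.0 * (1.0 / ns[ga] + 1.0 / ns[gb]))
        q = abs(means[ga] - means[gb]) / se
        p = float(stats.studentized_range.sf(q, k, df))
        pairs.append(PairComparison(ga, gb, float(q), p, p < alpha))
    letters = letter_display(list(by), [(p.group_a, p.group_b)
                                        for p in pairs if p.significant])
    return PairwiseReport("Tukey-Kramer HSD", alpha, pairs, letters)


def manova_roy(Y, groups) -> dict:
    """MANOVA via Roy's largest root.

    Returns a dict with theta (largest eigenvalue of E^-1 H), the upper-bound
    F approximation, its degrees of freedom, p, and the responses actually
    used (nearly dependent responses are dropped until the within-group SSCP
    matrix E is invertible; compositional data always loses one column).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be observations x responses")
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    N = Y.shape[0]
    used = list(range(Y.shape[1]))

    def sscp(cols):
        Yc = Y[:, cols]
        grand = Yc.mean(axis=0)
        H = np.zeros((len(cols), len(cols)))
        E = np.zeros_like(H)
        for g in labels:
            sub = Yc[groups == g]
            d = sub.mean(axis=0) - grand
            H += sub.shape[0] * np.outer(d, d)
            centered = sub - sub.mean(axis=0)
            E += centered.T @ centered
        return H, E

    H, E = sscp(used)
    while len(used) > 1 and (np.linalg.cond(E) > 1e10 or N <= len(used) + k):
        variances = np.diag(E).copy()
        drop = used[int(np.argmin(variances))]
        used = [c for c in used if c != drop]
        H, E = sscp(used)
    p_dim = len(used)
    if N <= p_dim + k:
        raise ValueError(f"need N > p + k ({N} <= {p_dim} + {k})")
    if np.linalg.cond(E) > 1e12:
        raise ValueError("within-group SSCP matrix is singular even after "
                         "response reduction")
    eigvals = np.linalg.eigvals(np.linalg.solve(E, H))
    theta = float(np.max(eigvals.real))
    r = max(p_dim, k - 1)
    df1 = r
    df2 = N - k - r + (k - 1)
    F = theta * df2 / df1
    return {"roy_largest_root": theta, "F": float(F), "df1": df1, "df2": df2,
            "p": float(stats.f.sf(F, df1, df2)), "responses_used": used,
            "n": N, "k": k}


def letter_display(group_names: list[str],
                   significant_pairs: list[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display via insert-and-absorb.

    Two groups share a letter iff they are NOT significantly different.
    """
    sets: list[set[str]] = [set(group_names)]
    for a, b in significant_pairs:
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets += [s - {a}, s - {b}]
            else:
                new_sets.append(s)
        # absorb: deduplicate, then drop sets contained in another
        uniq: list[set[str]] = []
        for s in new_sets:
            if s and s not in uniq:
                uniq.append(s)
        sets = [s for s in uniq if not any(s < t for t in uniq)] or [set()]
    order = {g: i for i, g in enumerate(group_names)}
    sets.sort(key=lambda s: min(order[g] for g in s) if s else len(order))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in group_names}
    for letter, s in zip(alphabet, sets):
        for g in group_names:
            if g in s:
                out[g] += letter
    return out
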