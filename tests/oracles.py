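"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own tally code paths: partitions are
enumerated as restricted-growth strings and scored from raw edge lists, and
the hypergeometric tail is summed in exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, log10


def all_label_vectors(n: int):
    """Every set partition of range(n) as a label vector (RGS order)."""
    labels = [0] * n

    def rec(i: int, kmax: int):
        if i == n:
            yield labels
            return
        for lab in range(kmax + 2):
            labels[i] = lab
            yield from rec(i + 1, max(kmax, lab))

    if n == 0:
        return
    yield from rec(1, 0)


def score_labels(labels, edges, degrees, objective: str = "D", lam: float = 0.5):
    """Score a label vector: D_lambda or Q computed from scratch."""
    n_mod: dict[int, int] = {}
    for lab in labels:
        n_mod[lab] = n_mod.get(lab, 0) + 1
    l_in = dict.fromkeys(n_mod, 0)
    d = dict.fromkeys(n_mod, 0)
    for u, v in edges:
        if labels[u] == labels[v]:
            l_in[labels[u]] += 1
    for i, lab in enumerate(labels):
        d[lab] += degrees[i]
    if objective == "D":
        # (4*lam*l_in - 2*(1-lam)*l_out)/n with l_out = d - 2*l_in
        return sum(
            (4.0 * lam * l_in[c] - 2.0 * (1.0 - lam) * (d[c] - 2 * l_in[c])) / n_mod[c]
            for c in n_mod
        )
    L = len(edges)
    return sum(l_in[c] / L - (d[c] / (2.0 * L)) ** 2 for c in n_mod)


def brute_force_best(net, objective: str = "D", lam: float = 0.5,
                     max_k: int | None = None, min_k: int = 1):
    """Exhaustive optimum of D_lambda or Q over all partitions of ``net``.

    Returns (best_value, frozenset of frozenset modules).  Feasible up to
    ~10 nodes (Bell(10) = 115,975 partitions).  ``min_k``/``max_k`` restrict
    the admissible number of modules.
    """
    nodes = sorted(net.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges]
    degrees = [net.degree[v] for v in nodes]
    best_val, best_labels = -float("inf"), None
    for labels in all_label_vectors(len(nodes)):
        k = max(labels) + 1
        if k < min_k or (max_k is not None and k > max_k):
            continue
        val = score_labels(labels, edges, degrees, objective, lam)
        if val > best_val:
            best_val, best_labels = val, list(labels)
    modules: dict[int, set] = {}
    for i, lab in enumerate(best_labels):
        modules.setdefault(lab, set()).add(nodes[i])
    return best_val, frozenset(frozenset(m) for m in modules.values())


def exact_hypergeom_tail_neg_log10(N: int, C: int, M: int, k: int) -> float:
    """-log10 P(X >= k), X hypergeometric(N, C, M), in exact rationals."""
    total = comb(N, M)
    tail = sum(comb(C, i) * comb(N - C, M - i) for i in range(k, min(C, M) + 1))
    p = Fraction(tail, total)
    if p == 1:
        return 0.0
    # math.log2 takes arbitrary-precision ints, so this is exact-safe
    from math import log2

    return (log2(p.denominator) - log2(p.numerator)) / log2(10)
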