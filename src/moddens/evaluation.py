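"""Performance measures for detected modules.

Against a planted partition: node-level precision under a greedy (or
Hungarian) one-to-one module matching.  Against a protein-complex
catalogue: hypergeometric overlap significance P_ol, the clustering-wise
sensitivity / positive predictive value / geometric accuracy of Brohee &
van Helden, and the frequency-product separation statistics, all computed
from a complexes x modules contingency table.

P_ol is the upper tail P(X >= k) of the hypergeometric distribution with
population N (the network size), |C| successes and |M| draws, evaluated in
log space; a module sharing no protein with a complex scores exactly 0 on
the -log10 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from .graph_core import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "MatchResult",
    "precision",
    "overlap_neg_log10_pvalue",
    "best_match",
    "contingency",
    "accuracy",
    "separation",
    "filter_small_modules",
    "read_complex_catalogue",
]

#: complex catalogue type: complex id -> set of member proteins
Catalogue = Mapping[str, frozenset]


def read_complex_catalogue(path, delimiter: str | None = None) -> dict[str, frozenset]:
    """Read a 2-column (complex_id, protein_id) TSV; proteins may belong to
    several complexes (the catalogue is not a partition)."""
    from .graph_core import _parse_rows

    groups: dict[str, set] = {}
    for _, fields in _parse_rows(path, delimiter, 2):
        groups.setdefault(fields[0], set()).add(fields[1])
    return {cid: frozenset(members) for cid, members in groups.items()}


def precision(detected: Partition, planted: Partition, method: str = "greedy") -> float:
    """Fraction of nodes classified into the right module.

    Planted modules are matched one-to-one to detected modules — greedily by
    descending overlap (ties: larger planted module first, then lexicographic
    labels) or by Hungarian maximum-total-overlap assignment — and a node
    counts as correct iff its detected module is the one matched to its
    planted module.
    """
    if detected.nodes != planted.nodes:
        raise ValueError("partitions must cover the same node set")
    n = len(planted.assignment)
    overlap: dict[tuple[str, str], int] = {}
    for node, plab in planted.assignment.items():
        key = (plab, detected.assignment[node])
        overlap[key] = overlap.get(key, 0) + 1
    if method == "greedy":
        pairs = sorted(
            overlap.items(),
            key=lambda kv: (-kv[1], -len(planted.modules[kv[0][0]]), kv[0][0], kv[0][1]),
        )
        matched: dict[str, str] = {}
        used: set[str] = set()
        for (plab, dlab), _count in pairs:
            if plab in matched or dlab in used:
                continue
            matched[plab] = dlab
            used.add(dlab)
    elif method == "hungarian":
        prows = sorted(planted.modules)
        dcols = sorted(detected.modules)
        cost = np.zeros((len(prows), len(dcols)))
        for (plab, dlab), count in overlap.items():
            cost[prows.index(plab), dcols.index(dlab)] = -count
        ri, ci = linear_sum_assignment(cost)
        matched = {prows[r]: dcols[c] for r, c in zip(ri, ci)}
    else:
        raise ValueError(f"unknown matching method {method!r}")
    correct = sum(
        count for (plab, dlab), count in overlap.items() if matched.get(plab) == dlab
    )
    return correct / n


def overlap_neg_log10_pvalue(N: int, complex_size: int, module_size: int, overlap: int) -> float:
    """-log10 of the hypergeometric upper tail P(X >= overlap).

    Population N, ``complex_size`` marked elements, ``module_size`` draws.
    An overlap of 0 returns 0 exactly (tail probability 1).
    """
    if not 0 <= overlap <= min(complex_size, module_size):
        raise ValueError(
            f"overlap {overlap} inconsistent with sizes ({complex_size}, {module_size})"
        )
    if max(complex_size, module_size) > N:
        raise ValueError("complex/module larger than the population")
    if overlap == 0:
        return 0.0
    logp = hypergeom.logsf(overlap - 1, N, complex_size, module_size)
    return float(-logp / np.log(10.0))


@dataclass(frozen=True)
class MatchResult:
    module: str
    module_size: int
    complex: str
    complex_size: int
    overlap: int
    neg_log10_pol: float


def best_match(modules: Partition, complexes: Catalogue, N: int) -> list[MatchResult]:
    """Best-matching complex (minimum P_ol) per module.

    Ties are broken by larger overlap, then smaller complex, then
    lexicographic complex id.  A module disjoint from every complex reports
    the first complex in that order with -log10 P_ol = 0.
    """
    universe = set()
    for members in complexes.values():
        universe |= set(members)
    if N < len(universe | set(modules.nodes)):
        raise ValueError("population N smaller than the union of modules and complexes")
    results = []
    for mlab in sorted(modules.modules):
        members = modules.modules[mlab]
        best: tuple | None = None
        for cid in sorted(complexes):
            cmembers = complexes[cid]
            k = len(members & cmembers)
            score = overlap_neg_log10_pvalue(N, len(cmembers), len(members), k)
            key = (-score, -k, len(cmembers), cid)
            if best is None or key < best[0]:
                best = (key, cid, k, score)
        _, cid, k, score = best
        results.append(
            MatchResult(
                module=mlab, module_size=len(members),
                complex=cid, complex_size=len(complexes[cid]),
                overlap=k, neg_log10_pol=score,
            )
        )
    return results


@dataclass(frozen=True)
class ContingencyTable:
    """Complexes x modules shared-protein counts over the complex-annotated
    universe, with complex sizes as row marginals."""

    values: np.ndarray  # (n_complexes, n_modules) int matrix
    row_labels: tuple
    col_labels: tuple
    complex_sizes: tuple  # N_i per complex (restricted to the universe)


def contingency(modules: Partition, complexes: Catalogue) -> ContingencyTable:
    """T_ij = |complex_i intersect module_j| over the catalogue universe.

    Module members outside the catalogue universe are ignored; complex
    proteins in no module still count toward the complex size N_i.
    """
    if not complexes or not modules.modules:
        raise ValueError("need a nonempty catalogue and a nonempty partition")
    universe = set()
    for members in complexes.values():
        universe |= set(members)
    rows = sorted(complexes)
    cols = sorted(modules.modules)
    T = np.zeros((len(rows), len(cols)), dtype=int)
    for i, cid in enumerate(rows):
        cmembers = complexes[cid]
        for j, mlab in enumerate(cols):
            T[i, j] = len(cmembers & (modules.modules[mlab] & universe))
    sizes = tuple(len(complexes[cid]) for cid in rows)
    return ContingencyTable(values=T, row_labels=tuple(rows), col_labels=tuple(cols), complex_sizes=sizes)


def accuracy(table: ContingencyTable) -> tuple[float, float, float]:
    """Clustering-wise (Sn, PPV, ACC).

    Sn is the size-weighted mean over complexes of the maximal fraction of a
    complex captured by one module; PPV the column-sum-weighted mean over
    modules of the maximal fraction of a module lying in one complex
    (zero-sum columns excluded); ACC their geometric mean.
    """
    T = table.values
    sizes = np.asarray(table.complex_sizes, dtype=float)
    if T.size == 0 or np.any(sizes <= 0):
        raise ValueError("empty table or nonpositive complex size")
    sn = float(T.max(axis=1).sum() / sizes.sum())
    col_sums = T.sum(axis=0)
    mask = col_sums > 0
    if not mask.any():
        ppv = 0.0
    else:
        ppv = float(T[:, mask].max(axis=0).sum() / col_sums[mask].sum())
    return sn, ppv, float(np.sqrt(sn * ppv))


def separation(table: ContingencyTable) -> tuple[float, float, float]:
    """(SEP_co, SEP_cl, SEP) frequency-product separation.

    Sep_ij is the product of the row-wise and column-wise relative
    frequencies of T_ij; SEP_co averages row sums of Sep over complexes,
    SEP_cl column sums over modules, SEP is their geometric mean.  Rows or
    columns with zero marginal contribute 0.
    """
    T = table.values.astype(float)
    if T.size == 0:
        raise ValueError("empty contingency table")
    row_sums = T.sum(axis=1, keepdims=True)
    col_sums = T.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        F_row = np.where(row_sums > 0, T / np.where(row_sums > 0, row_sums, 1), 0.0)
        F_col = np.where(col_sums > 0, T / np.where(col_sums > 0, col_sums, 1), 0.0)
    sep = F_row * F_col
    sep_co = float(sep.sum(axis=1).mean())
    sep_cl = float(sep.sum(axis=0).mean())
    return sep_co, sep_cl, float(np.sqrt(sep_co * sep_cl))


def filter_small_modules(p: Partition, min_size: int) -> Partition:
    """Drop modules smaller than ``min_size``; their nodes become unassigned.

    min_size = 1 is the identity.  Returns an empty partition (with a
    warning) if every module is below the threshold.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    keep = {
        node: lab
        for node, lab in p.assignment.items()
        if len(p.modules[lab]) >= min_size
    }
    if not keep and p.assignment:
        logger.warning("filter_small_modules(min_size=%d) removed every module", min_size)
    return Partition(keep)
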