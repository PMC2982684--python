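"""Simulated-annealing maximization of Q or D_lambda over partitions.

The annealer maintains a partition whose every module induces a connected
subgraph, and explores it with two kinds of moves:

* single-node moves — relabel one node to a module incident to it (picked
  through a random neighbour, so incident modules are sampled proportionally
  to their edges to the node) or to a fresh singleton module;
* collective moves — merge two modules sharing an edge, or split one module
  by a nested annealing that bipartitions its induced subgraph (both halves
  kept connected) maximizing the subgraph's own two-way modularity density.

Moves are accepted with the Metropolis rule on the cost C = -Q or -D_lambda:
probability 1 when the cost does not increase, exp(-dC/T) otherwise.  The
temperature T is cooled geometrically; a stage consists of a quota of
single-node and collective moves.  Connectivity of a mutated source module
is verified only for moves that would otherwise be accepted, which is
equivalent to rejecting disconnecting proposals outright but skips the
breadth-first search for moves the Metropolis rule already discards.

Single-node move costs are applied incrementally from per-module integer
tallies (n_i, l_in_i, d_i); collective moves recompute only the affected
modules' terms.  The returned partition's score is recomputed from scratch
as a guard against stale caching.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import networkx as nx

from .graph_core import Partition, induced_subgraph_connected
from .quality import QualityScore, modularity_density, modularity_q

logger = logging.getLogger(__name__)

__all__ = ["SASchedule", "SAState", "SAResult", "accept_probability", "sa_optimize"]


@dataclass
class SASchedule:
    """Annealing schedule.

    ``T0=None`` means auto-calibration: T0 is set so that a median uphill
    probe move is accepted with probability ~0.5.  Per stage the annealer
    attempts ``min(f1*n^2, max_single_per_stage)`` single-node moves and
    ``max(1, f2*n)`` collective moves, then multiplies T by ``cooling``.
    It stops when T < T0*t_min_factor, after ``stall_stages`` consecutive
    stages without an accepted move, or at ``max_stages``.
    """

    T0: float | None = None
    cooling: float = 0.95
    f1: float = 1.0
    f2: float = 0.05
    t_min_factor: float = 1e-4
    stall_stages: int = 3
    max_single_per_stage: int = 20000
    max_stages: int = 500
    nested_move_cap: int = 2000
    quench: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError(f"cooling must be in (0,1), got {self.cooling}")
        if self.T0 is not None and self.T0 <= 0:
            raise ValueError(f"T0 must be positive, got {self.T0}")
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("move count factors must be positive")
        if not 0.0 < self.t_min_factor < 1.0:
            raise ValueError("t_min_factor must be in (0,1)")
        if self.stall_stages < 1 or self.max_stages < 1:
            raise ValueError("stall_stages and max_stages must be >= 1")


def accept_probability(c_i: float, c_f: float, T: float) -> float:
    """Metropolis acceptance probability for a cost change at temperature T.

    1 for downhill or equal-cost moves, exp(-(c_f - c_i)/T) otherwise.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if c_f <= c_i:
        return 1.0
    return math.exp(-(c_f - c_i) / T)


class SAState:
    """Mutable annealing state over an integer-indexed view of the network.

    Exposes the current partition, its cost (-objective) and the incumbent
    best; used internally by :func:`sa_optimize` and directly by tests that
    exercise individual move proposals.
    """

    def __init__(self, net: nx.Graph, objective: str = "D", lam: float = 0.5):
        if objective not in ("Q", "D"):
            raise ValueError(f"objective must be 'Q' or 'D', got {objective!r}")
        if net.number_of_edges() < 1:
            raise ValueError("annealing requires a network with at least one edge")
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0,1], got {lam}")
        self.net = net
        self.objective = objective
        self.lam = lam
        self.nodes: list = sorted(net.nodes, key=str)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.adj: list[list[int]] = [
            [self.index[w] for w in net.adj[v]] for v in self.nodes
        ]
        self.deg = [len(a) for a in self.adj]
        self.edges = [(self.index[u], self.index[v]) for u, v in net.edges]
        self.n = len(self.nodes)
        self.L = len(self.edges)
        # coefficients: D term = (4*l - c2*d)/n ; Q term = l/L - (d/(2L))^2
        self._c2 = 2.0 * (1.0 - lam)
        # singleton start: every node its own module
        self.labels = list(range(self.n))
        self.mod_nodes: dict[int, set[int]] = {i: {i} for i in range(self.n)}
        self.mod_l: dict[int, int] = {i: 0 for i in range(self.n)}
        self.mod_d: dict[int, int] = {i: self.deg[i] for i in range(self.n)}
        self._next_label = self.n
        self.value = sum(
            self._term(1, 0, self.deg[i]) for i in range(self.n)
        )
        self.best_value = self.value
        self.best_labels = list(self.labels)

    # -- objective terms ------------------------------------------------
    def _term(self, n: int, l: int, d: int) -> float:
        if n == 0:
            return 0.0
        if self.objective == "D":
            return (4.0 * l - self._c2 * d) / n
        L = self.L
        return l / L - (d / (2.0 * L)) ** 2

    @property
    def cost(self) -> float:
        return -self.value

    @property
    def best_cost(self) -> float:
        return -self.best_value

    def partition(self, best: bool = True) -> Partition:
        labels = self.best_labels if best else self.labels
        return Partition(
            {self.nodes[i]: f"m{labels[i]}" for i in range(self.n)}
        ).relabel_canonical()

    # -- connectivity ----------------------------------------------------
    def _connected_without(self, members: set[int], v: int) -> bool:
        """Is the module `members` still connected after removing v?"""
        remaining = len(members) - 1
        if remaining <= 1:
            return True
        it = iter(members)
        start = next(it)
        if start == v:
            start = next(it)
        seen = {start}
        stack = [start]
        adj = self.adj
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w != v and w in members and w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == remaining

    def _note_accept(self):
        if self.value > self.best_value + 1e-12:
            self.best_value = self.value
            self.best_labels = list(self.labels)

    # -- single-node move -------------------------------------------------
    def try_single_move(self, rng: random.Random, T: float) -> bool:
        """Attempt one single-node relabel; returns True if applied."""
        v = rng.randrange(self.n)
        dv = self.deg[v]
        if dv == 0:
            return False
        s = self.labels[v]
        ns = len(self.mod_nodes[s])
        # target: module of a random neighbour, or a fresh singleton
        labels = self.labels
        adj_v = self.adj[v]
        if ns > 1 and rng.random() < 1.0 / (dv + 1):
            t = -1  # new module
        else:
            t = labels[adj_v[rng.randrange(dv)]]
            if t == s:
                return False
        k_vs = 0
        k_vt = 0
        for w in adj_v:
            lw = labels[w]
            if lw == s:
                k_vs += 1
            elif lw == t:
                k_vt += 1
        term = self._term
        ls, ds = self.mod_l[s], self.mod_d[s]
        delta = term(ns - 1, ls - k_vs, ds - dv) - term(ns, ls, ds)
        if t >= 0:
            nt, lt, dt = len(self.mod_nodes[t]), self.mod_l[t], self.mod_d[t]
            delta += term(nt + 1, lt + k_vt, dt + dv) - term(nt, lt, dt)
        else:
            delta += term(1, 0, dv)
        # Metropolis on cost = -value
        if delta < 0.0:
            x = -delta
            if x > 700.0 * T or rng.random() >= math.exp(-x / T):
                return False
        # connectivity clause: source module must stay connected
        if ns > 1 and not self._connected_without(self.mod_nodes[s], v):
            return False
        # apply
        self.mod_nodes[s].discard(v)
        self.mod_l[s] = self.mod_l[s] - k_vs
        self.mod_d[s] = self.mod_d[s] - dv
        if not self.mod_nodes[s]:
            del self.mod_nodes[s], self.mod_l[s], self.mod_d[s]
        if t < 0:
            t = self._next_label
            self._next_label += 1
            self.mod_nodes[t] = {v}
            self.mod_l[t] = 0
            self.mod_d[t] = dv
        else:
            self.mod_nodes[t].add(v)
            self.mod_l[t] += k_vt
            self.mod_d[t] += dv
        self.labels[v] = t
        self.value += delta
        self._note_accept()
        return True

    # -- zero-temperature quench -------------------------------------------
    def load_labels(self, labels: list[int]) -> None:
        """Reset the state to an explicit label vector, rebuilding tallies."""
        self.labels = list(labels)
        mod_nodes: dict[int, set[int]] = {}
        for i, lab in enumerate(self.labels):
            mod_nodes.setdefault(lab, set()).add(i)
        mod_l = {c: 0 for c in mod_nodes}
        mod_d = {c: 0 for c in mod_nodes}
        for u, w in self.edges:
            if self.labels[u] == self.labels[w]:
                mod_l[self.labels[u]] += 1
        for i, lab in enumerate(self.labels):
            mod_d[lab] += self.deg[i]
        self.mod_nodes, self.mod_l, self.mod_d = mod_nodes, mod_l, mod_d
        self._next_label = max(mod_nodes) + 1
        term = self._term
        self.value = sum(
            term(len(mod_nodes[c]), mod_l[c], mod_d[c]) for c in mod_nodes
        )
        if self.value > self.best_value:
            self.best_value = self.value
            self.best_labels = list(self.labels)

    def _descent_single_sweep(self) -> bool:
        """One deterministic pass of best-improvement single-node moves."""
        improved = False
        term = self._term
        labels = self.labels
        for v in range(self.n):
            dv = self.deg[v]
            if dv == 0:
                continue
            s = labels[v]
            ns = len(self.mod_nodes[s])
            k_inc: dict[int, int] = {}
            for w in self.adj[v]:
                lw = labels[w]
                k_inc[lw] = k_inc.get(lw, 0) + 1
            k_vs = k_inc.pop(s, 0)
            ls, ds = self.mod_l[s], self.mod_d[s]
            base = term(ns - 1, ls - k_vs, ds - dv) - term(ns, ls, ds)
            best_delta, best_t, best_k = 1e-12, None, 0
            for t in sorted(k_inc):
                nt, lt, dt = len(self.mod_nodes[t]), self.mod_l[t], self.mod_d[t]
                delta = base + term(nt + 1, lt + k_inc[t], dt + dv) - term(nt, lt, dt)
                if delta > best_delta:
                    best_delta, best_t, best_k = delta, t, k_inc[t]
            if ns > 1:
                delta = base + term(1, 0, dv)
                if delta > best_delta:
                    best_delta, best_t, best_k = delta, -1, 0
            if best_t is None:
                continue
            if ns > 1 and not self._connected_without(self.mod_nodes[s], v):
                continue
            t = best_t
            self.mod_nodes[s].discard(v)
            self.mod_l[s] -= k_vs
            self.mod_d[s] -= dv
            if not self.mod_nodes[s]:
                del self.mod_nodes[s], self.mod_l[s], self.mod_d[s]
            if t == -1:
                t = self._next_label
                self._next_label += 1
                self.mod_nodes[t] = {v}
                self.mod_l[t] = 0
                self.mod_d[t] = dv
            else:
                self.mod_nodes[t].add(v)
                self.mod_l[t] += best_k
                self.mod_d[t] += dv
            labels[v] = t
            self.value += best_delta
            improved = True
        return improved

    def _descent_merge_sweep(self) -> bool:
        """Apply the best profitable module merge; True if one was applied."""
        labels = self.labels
        cross: dict[tuple[int, int], int] = {}
        for u, w in self.edges:
            s, t = labels[u], labels[w]
            if s != t:
                key = (s, t) if s < t else (t, s)
                cross[key] = cross.get(key, 0) + 1
        term = self._term
        best_delta, best_pair, best_e = 1e-12, None, 0
        for (s, t) in sorted(cross):
            e_st = cross[(s, t)]
            ns, ls, ds = len(self.mod_nodes[s]), self.mod_l[s], self.mod_d[s]
            nt, lt, dt = len(self.mod_nodes[t]), self.mod_l[t], self.mod_d[t]
            delta = (
                term(ns + nt, ls + lt + e_st, ds + dt)
                - term(ns, ls, ds) - term(nt, lt, dt)
            )
            if delta > best_delta:
                best_delta, best_pair, best_e = delta, (s, t), e_st
        if best_pair is None:
            return False
        s, t = best_pair
        for v in self.mod_nodes[s]:
            labels[v] = t
        self.mod_nodes[t] |= self.mod_nodes[s]
        self.mod_l[t] += self.mod_l[s] + best_e
        self.mod_d[t] += self.mod_d[s]
        del self.mod_nodes[s], self.mod_l[s], self.mod_d[s]
        self.value += best_delta
        return True

    def _descent_split_sweep(self, rng: random.Random, move_cap: int) -> bool:
        """Split any module whose best found bipartition improves the value."""
        improved = False
        for c in sorted(self.mod_nodes):
            if c not in self.mod_nodes or len(self.mod_nodes[c]) < 2:
                continue
            members = sorted(self.mod_nodes[c])
            side, l0, l1, _cross = self._nested_bipartition(
                members, rng, T0=0.05, move_cap=move_cap
            )
            n0 = sum(1 for x in side if x == 0)
            n1 = len(members) - n0
            if n0 == 0 or n1 == 0:
                continue
            d0 = sum(self.deg[v] for v, s in zip(members, side) if s == 0)
            d1 = self.mod_d[c] - d0
            term = self._term
            delta = (
                term(n0, l0, d0) + term(n1, l1, d1)
                - term(len(members), self.mod_l[c], self.mod_d[c])
            )
            if delta <= 1e-12:
                continue
            new = self._next_label
            self._next_label += 1
            side1 = {v for v, s in zip(members, side) if s == 1}
            for v in side1:
                self.labels[v] = new
            self.mod_nodes[c] -= side1
            self.mod_nodes[new] = side1
            self.mod_l[c], self.mod_d[c] = l0, d0
            self.mod_l[new], self.mod_d[new] = l1, d1
            self.value += delta
            improved = True
        return improved

    def quench(self, rng: random.Random | None = None, max_rounds: int = 200,
               move_cap: int = 2000) -> None:
        """Greedy descent from the incumbent best state.

        Alternates best-improvement single-node sweeps, profitable module
        merges, and profitable module splits (found by the nested
        bipartitioner) until a local optimum under those move kinds is
        reached.  Deterministic for a given ``rng`` state; connectivity of
        every module is preserved.
        """
        if rng is None:
            rng = random.Random(0)
        self.load_labels(self.best_labels)
        for _ in range(max_rounds):
            moved = False
            while self._descent_single_sweep():
                moved = True
            if self._descent_merge_sweep():
                moved = True
            if self._descent_split_sweep(rng, move_cap):
                moved = True
            if not moved:
                break
        self._note_accept()

    # -- collective moves --------------------------------------------------
    def try_merge(self, rng: random.Random, T: float) -> bool:
        """Attempt to merge the two modules at the ends of a random edge."""
        labels = self.labels
        for _ in range(10):
            u, w = self.edges[rng.randrange(self.L)]
            s, t = labels[u], labels[w]
            if s != t:
                break
        else:
            return False
        if len(self.mod_nodes[s]) > len(self.mod_nodes[t]):
            s, t = t, s
        small = self.mod_nodes[s]
        e_st = 0
        for x in small:
            for y in self.adj[x]:
                if labels[y] == t:
                    e_st += 1
        term = self._term
        ns, ls, ds = len(small), self.mod_l[s], self.mod_d[s]
        nt, lt, dt = len(self.mod_nodes[t]), self.mod_l[t], self.mod_d[t]
        delta = term(ns + nt, ls + lt + e_st, ds + dt) - term(ns, ls, ds) - term(nt, lt, dt)
        if delta < 0.0:
            x = -delta
            if x > 700.0 * T or rng.random() >= math.exp(-x / T):
                return False
        for x in small:
            labels[x] = t
        self.mod_nodes[t] |= small
        self.mod_l[t] = lt + ls + e_st
        self.mod_d[t] = dt + ds
        del self.mod_nodes[s], self.mod_l[s], self.mod_d[s]
        self.value += delta
        self._note_accept()
        return True

    def _nested_bipartition(self, members: list[int], rng: random.Random, T0: float, move_cap: int):
        """Nested annealing: bipartition the induced subgraph of `members`
        maximizing its own isolated two-way D_lambda, both halves connected.

        Returns (side list, l0, l1, cross) for the best bipartition found.
        """
        nc = len(members)
        pos = {v: i for i, v in enumerate(members)}
        ladj: list[list[int]] = [[] for _ in range(nc)]
        for i, v in enumerate(members):
            for w in self.adj[v]:
                j = pos.get(w)
                if j is not None:
                    ladj[i].append(j)
        # seed side 0 with a connected half grown from a random node
        side = [1] * nc
        start = rng.randrange(nc)
        side[start] = 0
        frontier = [start]
        count = 1
        target = max(1, nc // 2)
        while frontier and count < target:
            u = frontier.pop()
            for w in ladj[u]:
                if side[w] == 1:
                    side[w] = 0
                    frontier.append(w)
                    count += 1
                    if count >= target:
                        break
        # side 1 (the complement of the grown half) may be disconnected:
        # keep its lowest-index component, fold the rest into side 0.  Every
        # side-1 component borders side 0 (the module is connected), so
        # side 0 stays connected.
        ones = [i for i in range(nc) if side[i] == 1]
        if not ones:  # degenerate: grow consumed everything
            side[start] = 1
            ones = [start]
        seen_comp: set[int] = set()
        first_comp: set[int] | None = None
        for root in ones:
            if root in seen_comp:
                continue
            comp = {root}
            stack = [root]
            while stack:
                u = stack.pop()
                for w in ladj[u]:
                    if side[w] == 1 and w not in comp:
                        comp.add(w)
                        stack.append(w)
            seen_comp |= comp
            if first_comp is None:
                first_comp = comp
            else:
                for u in comp:
                    side[u] = 0
        l0 = l1 = cross = 0
        for i in range(nc):
            for j in ladj[i]:
                if j > i:
                    if side[i] == side[j]:
                        if side[i] == 0:
                            l0 += 1
                        else:
                            l1 += 1
                    else:
                        cross += 1
        n0 = sum(1 for x in side if x == 0)
        n1 = nc - n0
        c2 = self._c2

        def d2(n0, n1, l0, l1, cross):
            # two-way D_lambda of the isolated subgraph: each side's l_out
            # is the cross-edge count
            val = 0.0
            if n0:
                val += (4.0 * self.lam * l0 - c2 * cross) / n0
            if n1:
                val += (4.0 * self.lam * l1 - c2 * cross) / n1
            return val

        cur = d2(n0, n1, l0, l1, cross)
        best = (list(side), l0, l1, cross, cur)
        budget = min(10 * nc * nc, move_cap)
        if budget <= 0 or nc < 2:
            return best[:4]
        T = max(T0, 1e-12)
        cool = (1e-3) ** (1.0 / budget)
        side_sets = [set(i for i in range(nc) if side[i] == 0),
                     set(i for i in range(nc) if side[i] == 1)]
        for _ in range(budget):
            u = rng.randrange(nc)
            a = side[u]
            b = 1 - a
            if len(side_sets[a]) == 1:
                T *= cool
                continue
            k_ua = sum(1 for w in ladj[u] if side[w] == a)
            k_ub = len(ladj[u]) - k_ua
            if k_ub == 0 and len(side_sets[b]) > 0:
                T *= cool
                continue  # would disconnect the target side
            if a == 0:
                nl0, nl1 = l0 - k_ua, l1 + k_ub
                nn0, nn1 = n0 - 1, n1 + 1
            else:
                nl0, nl1 = l0 + k_ub, l1 - k_ua
                nn0, nn1 = n0 + 1, n1 - 1
            ncross = cross + k_ua - k_ub
            nval = d2(nn0, nn1, nl0, nl1, ncross)
            delta = nval - cur
            if delta < 0.0:
                x = -delta
                if x > 700.0 * T or rng.random() >= math.exp(-x / T):
                    T *= cool
                    continue
            # source side must stay connected
            sset = side_sets[a]
            if not self._local_connected_without(sset, u, ladj):
                T *= cool
                continue
            sset.discard(u)
            side_sets[b].add(u)
            side[u] = b
            l0, l1, cross, cur = nl0, nl1, ncross, nval
            n0, n1 = nn0, nn1
            if cur > best[4] + 1e-12:
                best = (list(side), l0, l1, cross, cur)
            T *= cool
        return best[:4]

    @staticmethod
    def _local_connected_without(members: set[int], v: int, ladj) -> bool:
        remaining = len(members) - 1
        if remaining <= 1:
            return True
        it = iter(members)
        start = next(it)
        if start == v:
            start = next(it)
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for w in ladj[u]:
                if w != v and w in members and w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == remaining

    def try_split(self, rng: random.Random, T: float, T0: float, move_cap: int) -> bool:
        """Attempt to split one module via the nested annealing."""
        mods = [c for c, mem in self.mod_nodes.items() if len(mem) >= 2]
        if not mods:
            return False
        c = mods[rng.randrange(len(mods))]
        members = sorted(self.mod_nodes[c])
        side, l0, l1, cross = self._nested_bipartition(
            members, rng, T0 / 10.0, move_cap
        )
        n0 = sum(1 for x in side if x == 0)
        n1 = len(members) - n0
        if n0 == 0 or n1 == 0:
            return False
        d0 = sum(self.deg[v] for v, s in zip(members, side) if s == 0)
        d1 = self.mod_d[c] - d0
        term = self._term
        delta = (
            term(n0, l0, d0)
            + term(n1, l1, d1)
            - term(len(members), self.mod_l[c], self.mod_d[c])
        )
        if delta < 0.0:
            x = -delta
            if x > 700.0 * T or rng.random() >= math.exp(-x / T):
                return False
        new = self._next_label
        self._next_label += 1
        side1 = {v for v, s in zip(members, side) if s == 1}
        for v in side1:
            self.labels[v] = new
        self.mod_nodes[c] -= side1
        self.mod_nodes[new] = side1
        self.mod_l[c], self.mod_d[c] = l0, d0
        self.mod_l[new], self.mod_d[new] = l1, d1
        self.value += delta
        self._note_accept()
        return True

    def try_collective_move(self, rng: random.Random, T: float, T0: float, move_cap: int) -> bool:
        if len(self.mod_nodes) >= 2 and rng.random() < 0.5:
            return self.try_merge(rng, T)
        return self.try_split(rng, T, T0, move_cap)

    # -- spec-level proposal API (used by tests; not the hot path) --------
    def propose_single_move(self, rng: random.Random, max_tries: int = 200) -> Partition | None:
        """Propose one connectivity-legal single-node relabel as a Partition.

        Returns None if no legal candidate was found in ``max_tries`` draws.
        """
        labels = self.labels
        for _ in range(max_tries):
            v = rng.randrange(self.n)
            if self.deg[v] == 0:
                continue
            s = labels[v]
            ns = len(self.mod_nodes[s])
            incident = sorted({labels[w] for w in self.adj[v]} - {s})
            options: list[int] = list(incident)
            if ns > 1:
                options.append(-1)
            if not options:
                continue
            t = options[rng.randrange(len(options))]
            if ns > 1 and not self._connected_without(self.mod_nodes[s], v):
                continue
            cand = list(labels)
            cand[v] = self._next_label if t < 0 else t
            return Partition(
                {self.nodes[i]: f"m{cand[i]}" for i in range(self.n)}
            ).relabel_canonical()
        return None

    def propose_collective_move(
        self, rng: random.Random, move_cap: int = 2000, max_tries: int = 50
    ) -> Partition | None:
        """Propose a merge of two adjacent modules or a nested-SA split."""
        for _ in range(max_tries):
            if len(self.mod_nodes) >= 2 and rng.random() < 0.5:
                u, w = self.edges[rng.randrange(self.L)]
                s, t = self.labels[u], self.labels[w]
                if s == t:
                    continue
                cand = [t if x == s else x for x in self.labels]
            else:
                mods = [c for c, mem in self.mod_nodes.items() if len(mem) >= 2]
                if not mods:
                    continue
                c = mods[rng.randrange(len(mods))]
                members = sorted(self.mod_nodes[c])
                side, *_ = self._nested_bipartition(members, rng, 0.01, move_cap)
                if len(set(side)) < 2:
                    continue
                cand = list(self.labels)
                new = self._next_label
                for v, sd in zip(members, side):
                    if sd == 1:
                        cand[v] = new
            return Partition(
                {self.nodes[i]: f"m{cand[i]}" for i in range(self.n)}
            ).relabel_canonical()
        return None


@dataclass
class SAResult:
    partition: Partition
    score: QualityScore
    trace: list = field(default_factory=list)  # (stage, T, cost, best_cost, accepted)


def _calibrate_T0(state: SAState, rng: random.Random, probes: int = 100) -> float:
    """T0 such that the median uphill probe move is accepted w.p. ~0.5."""
    uphill: list[float] = []
    snapshot = rng.getstate()
    for _ in range(probes * 5):
        if len(uphill) >= probes:
            break
        v = rng.randrange(state.n)
        if state.deg[v] == 0:
            continue
        s = state.labels[v]
        adj_v = state.adj[v]
        t = state.labels[adj_v[rng.randrange(len(adj_v))]]
        k_vs = sum(1 for w in adj_v if state.labels[w] == s)
        k_vt = sum(1 for w in adj_v if state.labels[w] == t)
        if t == s:
            continue
        ns = len(state.mod_nodes[s])
        term = state._term
        ls, ds = state.mod_l[s], state.mod_d[s]
        nt, lt, dt = len(state.mod_nodes[t]), state.mod_l[t], state.mod_d[t]
        dv = state.deg[v]
        delta = (
            term(ns - 1, ls - k_vs, ds - dv)
            + term(nt + 1, lt + k_vt, dt + dv)
            - term(ns, ls, ds)
            - term(nt, lt, dt)
        )
        if delta < 0:
            uphill.append(-delta)
    rng.setstate(snapshot)
    if not uphill:
        return 1.0
    uphill.sort()
    med = uphill[len(uphill) // 2]
    return max(med / math.log(2.0), 1e-6)


def sa_optimize(
    net: nx.Graph,
    objective: str = "D",
    lam: float = 0.5,
    schedule: SASchedule | None = None,
) -> SAResult:
    """Anneal from the all-singletons partition and return the incumbent best.

    Every returned module induces a connected subgraph; the reported score
    is recomputed from the returned partition.  Bit-reproducible for a fixed
    ``schedule.seed``.
    """
    schedule = schedule or SASchedule()
    schedule.validate()
    state = SAState(net, objective=objective, lam=lam)
    rng = random.Random(schedule.seed)
    T0 = schedule.T0 if schedule.T0 is not None else _calibrate_T0(state, rng)
    n_single = max(1, min(int(schedule.f1 * state.n * state.n), schedule.max_single_per_stage))
    n_coll = max(1, int(schedule.f2 * state.n))
    T = T0
    T_min = T0 * schedule.t_min_factor
    trace: list[tuple] = []
    stalls = 0
    for stage in range(schedule.max_stages):
        accepted = 0
        for _ in range(n_single):
            if state.try_single_move(rng, T):
                accepted += 1
        for _ in range(n_coll):
            if state.try_collective_move(rng, T, T0, schedule.nested_move_cap):
                accepted += 1
        trace.append((stage, T, state.cost, state.best_cost, accepted))
        stalls = stalls + 1 if accepted == 0 else 0
        if stalls >= schedule.stall_stages:
            break
        T *= schedule.cooling
        if T < T_min:
            break
    if schedule.quench:
        state.quench(rng, move_cap=schedule.nested_move_cap)
    part = state.partition(best=True)
    if objective == "Q":
        score = modularity_q(net, part)
    else:
        score = modularity_density(net, part, lam)
    # paranoia: the incumbent bookkeeping and the from-scratch value agree
    if abs(score.value - state.best_value) > 1e-6 * max(1.0, abs(score.value)):
        logger.warning(
            "incumbent value %.9f differs from recomputed %.9f",
            state.best_value, score.value,
        )
    for members in part.modules.values():
        if not induced_subgraph_connected(net, members):  # pragma: no cover
            raise AssertionError("annealer returned a disconnected module")
    return SAResult(partition=part, score=score, trace=trace)
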