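"""Detect planted modules with both optimizers and score the recovery.

Generates a small planted-clique benchmark (4 cliques, mean external degree
3), runs the simulated-annealing D-maximizer and the spectral SpeMD scan,
and reports node precision against the planted truth.  Precision 1.0 means
every node was returned in the module matched to its planted clique.
"""

from moddens import SASchedule, generate, precision, sa_optimize, spemd_detect

inst = generate(m=2, n1=10, n2=15, k_out=3, seed=5)
net = inst.network
print(f"benchmark: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges, "
      f"{inst.nc} planted cliques")

sa = sa_optimize(net, objective="D", schedule=SASchedule(seed=1))
print(f"SA (MD)  : {sa.partition.m} modules, D = {sa.score.value:.3f}, "
      f"precision = {precision(sa.partition, inst.planted):.3f}")

sp = spemd_detect(net, K=8, seed=1)
print(f"SpeMD    : best k = {sp.best_k}, D = {sp.best_score.value:.3f}, "
      f"precision = {precision(sp.best_partition, inst.planted):.3f}")
print(f"           per-k D scan: "
      + ", ".join(f"k={k}: {v:.2f}" for k, v in sorted(sp.per_k_scores.items())))
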