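"""Statistical-parsimony haplotype network at a probability-based step limit.

A statistical parsimony network connects haplotypes by single mutational
steps, joining ever more distant haplotypes until the number of steps exceeds
a "connection limit": the largest number of mutational differences that can
still be attributed, at a given confidence (conventionally 95%), to unique
single substitutions rather than superimposed change at a site.  Haplotypes
further apart than the limit remain in separate components, so the component
count doubles as a screen for deeply divergent (potentially cryptic) lineages.

The probability-of-parsimony model pinned here is the uniform multiple-hit
model: conditional on j mutational events over m independent sites, the
events are homoplasy-free exactly when they strike j distinct sites, which
has probability

    P(j; m) = prod_{i=0}^{j-1} (m - i) / m.

The connection limit is the largest j with P(j; m) >= confidence (at least
1).  Any multiple hit at a site — back, parallel, or onward substitution —
is treated as a parsimony violation.  An explicit integer step-limit
override is available for mimicking other programs' realized limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .haplotypes import UNAMBIGUOUS, HaplotypeTable

logger = logging.getLogger(__name__)


def parsimony_probability(steps: int, seq_length: int) -> float:
    """Probability that `steps` mutations over `seq_length` sites hit distinct sites."""
    if steps < 0:
        raise ValueError("steps must be non-negative")
    p = 1.0
    for i in range(steps):
        p *= (seq_length - i) / seq_length
        if p <= 0.0:
            return 0.0
    return p


def parsimony_connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest number of steps whose probability of parsimony is >= confidence.

    Always at least 1; degenerate sequence lengths return 1.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    j = 1
    while j < seq_length and parsimony_probability(j + 1, seq_length) >= confidence:
        j += 1
    return j


def mutational_distance(a: str, b: str) -> int:
    """Number of differing sites where both haplotypes are unambiguous."""
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x in UNAMBIGUOUS and y in UNAMBIGUOUS
    )


@dataclass
class ParsimonyNetwork:
    """Unit-step haplotype network with inferred intermediates.

    Nodes are observed haplotype ids plus inferred intermediate ids
    (``mv1``, ``mv2``, ...); every edge represents exactly one mutational
    step.  ``components`` partitions the observed haplotypes.
    """

    graph: nx.Graph
    components: list[list[str]]
    connection_limit: int
    observed: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def intermediates(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "inferred"]


def build_network(haps: HaplotypeTable, limit: int) -> ParsimonyNetwork:
    """Agglomeratively connect haplotype clusters up to ``limit`` steps.

    Clusters are joined in order of increasing mutational distance
    d = 1, 2, ..., limit; a join at distance d inserts d-1 degree-2
    intermediate nodes along one shortest mutational path (sites mutated
    left-to-right along the alignment — any shortest path is equally
    parsimonious).  Ties in join order are resolved by lexicographic
    haplotype id.
    """
    if haps.n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if limit < 1:
        raise ValueError("limit must be >= 1")

    ids = haps.haplotype_ids
    seqs = dict(zip(ids, haps.haplotype_sequences))
    totals = haps.total_counts()

    g = nx.Graph()
    for h in ids:
        g.add_node(h, kind="observed", total_count=int(totals[h]))

    # cluster id -> member observed haplotypes (union-find by dict)
    cluster_of = {h: h for h in ids}

    def find(h: str) -> str:
        while cluster_of[h] != h:
            cluster_of[h] = cluster_of[cluster_of[h]]
            h = cluster_of[h]
        return h

    pairs = sorted(
        ((mutational_distance(seqs[a], seqs[b]), a, b)
         for i, a in enumerate(ids) for b in ids[i + 1:]),
        key=lambda t: (t[0], t[1], t[2]),
    )

    n_inferred = 0
    for d, a, b in pairs:
        if d > limit:
            break
        if find(a) == find(b):
            continue
        # insert d-1 intermediates on a left-to-right shortest path a -> b
        prev = a
        seq = list(seqs[a])
        diff_sites = [
            j for j, (x, y) in enumerate(zip(seqs[a], seqs[b]))
            if x != y and x in UNAMBIGUOUS and y in UNAMBIGUOUS
        ]
        for step, j in enumerate(diff_sites):
            seq[j] = seqs[b][j]
            if step == len(diff_sites) - 1:
                node = b
            else:
                n_inferred += 1
                node = f"mv{n_inferred}"
                g.add_node(node, kind="inferred", total_count=0)
            g.add_edge(prev, node)
            prev = node
        cluster_of[find(a)] = find(b)

    comp_of = {h: find(h) for h in ids}
    components: list[list[str]] = []
    seen: dict[str, int] = {}
    for h in ids:  # report components in haplotype input order
        root = comp_of[h]
        if root not in seen:
            seen[root] = len(components)
            components.append([])
        components[seen[root]].append(h)

    logger.info(
        "parsimony network: %d haplotypes, %d inferred intermediates, "
        "%d component(s) at limit %d steps",
        len(ids), n_inferred, len(components), limit,
    )
    return ParsimonyNetwork(g, components, limit, observed=list(ids))


def write_network(net: ParsimonyNetwork, out_prefix: str) -> None:
    """Write edge list CSV, node table CSV, and GraphML."""
    import csv

    with open(f"{out_prefix}_edges.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_a", "node_b"])
        for a, b in sorted(net.graph.edges()):
            w.writerow([a, b])
    with open(f"{out_prefix}_nodes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "kind", "total_count"])
        for n, d in sorted(net.graph.nodes(data=True)):
            w.writerow([n, d["kind"], d["total_count"]])
    nx.write_graphml(net.graph, f"{out_prefix}.graphml")
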