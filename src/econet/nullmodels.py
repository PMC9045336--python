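"""Degree-preserving randomized ensembles and significance of topology."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import EcoNetwork

__all__ = ["NullEnsembleSummary", "rewire", "null_ensemble", "DEFAULT_NULL_REPS"]

#: Randomizations per empirical network.
DEFAULT_NULL_REPS = 100


@dataclass
class NullEnsembleSummary:
    """Per-metric empirical value vs randomized mean/sd with z and p."""

    table: pd.DataFrame
    n_reps: int

    def to_frame(self) -> pd.DataFrame:
        return self.table


def rewire(net: EcoNetwork, n_swaps: int | None = None, seed: int | None = None) -> EcoNetwork:
    """Maslov-Sneppen double-edge swaps preserving the degree sequence.

    ``n_swaps`` is the number of swap *attempts* (default 10 x L).  Edge
    (weight, sign) pairs are reassigned by a random permutation of the
    original multiset, decoupling signs from the rewired topology.
    """
    g = net.graph
    L = g.number_of_edges()
    if L < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    if n_swaps is None:
        n_swaps = 10 * L
    edges = [tuple(e) for e in g.edges()]
    edge_set = set(frozenset(e) for e in edges)
    swapped = 0
    for _ in range(n_swaps):
        i, j = rng.integers(0, L, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, b), (c, d) -> (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        swapped += 1
    if swapped == 0:
        warnings.warn("no valid swap found; returning input topology", stacklevel=2)
    attrs = [(d["weight"], d["sign"]) for _, _, d in g.edges(data=True)]
    perm = rng.permutation(L)
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    for (u, v), k in zip(edges, perm):
        w, s = attrs[k]
        out.add_edge(u, v, weight=w, sign=s)
    return EcoNetwork(out, st=net.st, provenance=net.provenance)


def null_ensemble(
    net: EcoNetwork,
    metrics: dict,
    reps: int = DEFAULT_NULL_REPS,
    seed: int | None = None,
) -> NullEnsembleSummary:
    """Evaluate ``metrics`` (name -> callable(EcoNetwork) -> float) on ``reps``
    degree-preserving randomizations and score the empirical values.

    z = (empirical - null mean) / null sd; two-sided normal p.  Metrics whose
    null sd is 0 get ``p = NaN`` and ``degenerate = True``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    empirical = {name: float(fn(net)) for name, fn in metrics.items()}
    null_vals: dict = {name: [] for name in metrics}
    for _ in range(reps):
        rnd = rewire(net, seed=int(rng.integers(0, 2**31 - 1)))
        for name, fn in metrics.items():
            null_vals[name].append(float(fn(rnd)))
    rows = []
    for name in metrics:
        vals = np.asarray(null_vals[name])
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd > 0:
            z = (empirical[name] - mu) / sd
            p = 2.0 * stats.norm.sf(abs(z))
            degenerate = False
        else:
            z, p, degenerate = float("nan"), float("nan"), True
        rows.append(
            {"metric": name, "empirical": empirical[name], "null_mean": mu,
             "null_sd": sd, "z": z, "p": p, "degenerate": degenerate}
        )
    return NullEnsembleSummary(pd.DataFrame(rows).set_index("metric"), reps)
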