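"""Community stability statistics.

Cohesion quantifies per-sample connectivity: observed pairwise correlations
on relative abundances are corrected by a taxa-shuffle null, averaged into
per-taxon positive/negative connectedness values, and combined with each
sample's abundances into positive and negative cohesion.  Vulnerability
measures the relative drop in global efficiency when a node is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import EcoNetwork
from .tables import AbundanceTable

__all__ = [
    "CohesionResult",
    "VulnerabilityResult",
    "cohesion",
    "np_ratio_summary",
    "vulnerability",
    "negative_link_ratio",
    "DEFAULT_COHESION_REPS",
]

#: Default number of taxa-shuffle null replicates.
DEFAULT_COHESION_REPS = 200


@dataclass
class CohesionResult:
    """Per-taxon connectedness and per-sample cohesion values.

    ``connectedness`` has columns ``pos``/``neg`` indexed by taxon;
    ``samples`` has columns ``cohesion_pos`` (>= 0), ``cohesion_neg`` (<= 0)
    and ``np_ratio`` (NaN where cohesion_pos = 0).
    """

    connectedness: pd.DataFrame
    samples: pd.DataFrame
    corrected: pd.DataFrame
    null_reps: int
    seed: int | None


def cohesion(
    table: AbundanceTable,
    null_reps: int = DEFAULT_COHESION_REPS,
    seed: int | None = None,
    persistence: float = 0.2,
    method: str = "pearson",
    connectedness_denominator: str = "taxa",
    renormalize_null: bool = True,
) -> CohesionResult:
    """Positive and negative cohesion per sample.

    Steps: (1) pairwise correlations between taxa on relative abundances;
    (2) null expectation per pair from ``null_reps`` independent shuffles of
    each taxon's abundances across samples; (3) corrected correlation =
    observed - null mean; (4) per-taxon connectedness = average positive
    (resp. negative) corrected correlation with the other taxa; (5) cohesion
    of sample s = sum_j abundance(s, j) * connectedness(j).

    ``connectedness_denominator`` controls step 4: ``"taxa"`` (default)
    divides the summed positive (negative) corrected correlations by the
    number of other taxa; ``"signed"`` divides by the number of pairs of
    that sign only.

    ``renormalize_null`` (default True) renormalizes each shuffled sample
    back to relative abundances before computing null correlations, so the
    null expectation carries the same compositional-closure bias (about
    -1/(S-1) between independent taxa) as the observed correlations and the
    correction cancels it.

    Taxa present in fewer than ``persistence`` of the samples are excluded
    before correlation.  Deterministic given ``seed``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if connectedness_denominator not in ("taxa", "signed"):
        raise ValueError("connectedness_denominator must be 'taxa' or 'signed'")
    n_samples = table.data.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples for cohesion")
    if n_samples < 10:
        warnings.warn("fewer than 10 samples; cohesion will be noisy", stacklevel=2)

    df = table.data
    prevalence = (df > 0).sum(axis=1) / n_samples
    df = df.loc[prevalence >= persistence]
    if df.shape[0] < 2:
        raise ValueError("fewer than 2 taxa pass the persistence filter")
    raw = df.to_numpy(dtype=float).T  # samples x taxa

    def _transform(mat):
        if method == "spearman":
            from scipy.stats import rankdata

            return rankdata(mat, axis=0)
        return mat

    n_taxa = raw.shape[1]
    obs = np.corrcoef(_transform(raw), rowvar=False)
    obs = np.nan_to_num(obs, nan=0.0)

    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    for _ in range(null_reps):
        order = np.argsort(rng.random(raw.shape), axis=0)
        shuffled = np.take_along_axis(raw, order, axis=0)
        if renormalize_null:
            totals = shuffled.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            shuffled = shuffled / totals
        c = np.corrcoef(_transform(shuffled), rowvar=False)
        null_sum += np.nan_to_num(c, nan=0.0)
    corrected = obs - null_sum / null_reps
    np.fill_diagonal(corrected, 0.0)

    pos = np.where(corrected > 0, corrected, 0.0)
    neg = np.where(corrected < 0, corrected, 0.0)
    if connectedness_denominator == "taxa":
        conn_pos = pos.sum(axis=0) / (n_taxa - 1)
        conn_neg = neg.sum(axis=0) / (n_taxa - 1)
    else:
        n_pos = (corrected > 0).sum(axis=0)
        n_neg = (corrected < 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            conn_pos = np.where(n_pos > 0, pos.sum(axis=0) / np.maximum(n_pos, 1), 0.0)
            conn_neg = np.where(n_neg > 0, neg.sum(axis=0) / np.maximum(n_neg, 1), 0.0)

    abund = df.to_numpy(dtype=float)  # taxa x samples
    coh_pos = abund.T @ conn_pos
    coh_neg = abund.T @ conn_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        np_ratio = np.where(coh_pos > 0, np.abs(coh_neg) / coh_pos, np.nan)
    if np.isnan(np_ratio).any():
        warnings.warn("np_ratio undefined for samples with zero positive cohesion",
                      stacklevel=2)

    taxa = list(df.index)
    return CohesionResult(
        connectedness=pd.DataFrame({"pos": conn_pos, "neg": conn_neg}, index=taxa),
        samples=pd.DataFrame(
            {"cohesion_pos": coh_pos, "cohesion_neg": coh_neg, "np_ratio": np_ratio},
            index=list(df.columns),
        ),
        corrected=pd.DataFrame(corrected, index=taxa, columns=taxa),
        null_reps=null_reps,
        seed=seed,
    )


def np_ratio_summary(result: CohesionResult, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean and standard error of cohesion and N:P.

    ``groups`` maps sample id -> group label.  Groups with fewer than 2
    samples are excluded with a warning.
    """
    df = result.samples.copy()
    df["group"] = pd.Series(groups).reindex(df.index)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        if len(sub) < 2:
            warnings.warn(f"group {g!r} has < 2 samples; excluded", stacklevel=2)
            continue
        rec = {"group": g, "n": len(sub)}
        for col in ("cohesion_pos", "cohesion_neg", "np_ratio"):
            vals = sub[col].dropna()
            rec[f"{col}_mean"] = float(vals.mean())
            rec[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("group")


@dataclass
class VulnerabilityResult:
    global_efficiency: float
    node_vulnerability: pd.Series
    network_vulnerability: float


def _efficiency(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))  # ordered pairs; equals unordered mean


def vulnerability(net: EcoNetwork) -> VulnerabilityResult:
    """Relative efficiency loss from single-node removal.

    v_i = (E - E_i) / E where E_i is the global efficiency of the graph
    without node i (computed over the remaining n - 1 nodes).  Network
    vulnerability is the maximum v_i.
    """
    g = net.skeleton()
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    e = _efficiency(g)
    if e == 0:
        raise ValueError("edgeless network: global efficiency is 0")
    vals = {}
    for node in g.nodes:
        h = g.copy()
        h.remove_node(node)
        vals[node] = (e - _efficiency(h)) / e
    series = pd.Series(vals)
    return VulnerabilityResult(
        global_efficiency=float(e),
        node_vulnerability=series,
        network_vulnerability=float(series.max()),
    )


def negative_link_ratio(net: EcoNetwork) -> float:
    """Fraction of edges with negative sign."""
    if net.n_links == 0:
        raise ValueError("empty network")
    return net.n_negative / net.n_links
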