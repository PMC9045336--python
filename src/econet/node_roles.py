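"""Within-module (Zi) and among-module (Pi) connectivity, node role
classification, keystone tables and keystone-diversity screening.

Zi = (k_ib - mean_b) / sd_b, where k_ib is node i's number of links to
other members of its own module b, and mean/sd are taken over the
within-module degrees of module b's members.  Pi = 1 - sum_c (k_ic / k_i)^2
over all modules c.  Role thresholds: hubs at Zi > 2.5, connectors at
Pi > 0.62 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import EcoNetwork
from .topology import ModulePartition

__all__ = [
    "ZI_THRESHOLD",
    "PI_THRESHOLD",
    "KEYSTONE_ROLES",
    "zi_pi",
    "classify_role",
    "role_table",
    "keystone_table",
    "keystone_diversity_association",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

#: Roles regarded as potential keystone taxa.
KEYSTONE_ROLES = ("network_hub", "module_hub", "connector")


def zi_pi(net: EcoNetwork, part: ModulePartition) -> pd.DataFrame:
    """Per-node Zi and Pi given a module partition covering all nodes.

    A module whose members all share the same within-module degree has
    sd = 0; its members get Zi = 0 by convention (flagged in the
    ``degenerate_module`` column).
    """
    g = net.skeleton()
    missing = [n for n in g.nodes if n not in part.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    nodes = list(g.nodes)
    module_of = part.assignment
    modules = sorted(set(module_of[n] for n in nodes))
    # k_ic: links of node i into each module c
    k_ic = {n: {m: 0 for m in modules} for n in nodes}
    for u, v in g.edges:
        k_ic[u][module_of[v]] += 1
        k_ic[v][module_of[u]] += 1
    # within-module degree statistics per module
    within = {n: k_ic[n][module_of[n]] for n in nodes}
    stats_by_module = {}
    for m in modules:
        vals = np.array([within[n] for n in nodes if module_of[n] == m], dtype=float)
        stats_by_module[m] = (vals.mean(), vals.std(ddof=0))
    rows = []
    for n in nodes:
        m = module_of[n]
        mu, sd = stats_by_module[m]
        degenerate = sd == 0
        zi = 0.0 if degenerate else (within[n] - mu) / sd
        k_i = sum(k_ic[n].values())
        if k_i == 0:
            raise ValueError(f"node {n!r} has no links")
        pi = 1.0 - sum((k / k_i) ** 2 for k in k_ic[n].values())
        rows.append(
            {"otu_id": n, "zi": zi, "pi": pi, "module": m, "degree": k_i,
             "within_module_degree": within[n], "degenerate_module": degenerate}
        )
    return pd.DataFrame(rows).set_index("otu_id")


def classify_role(
    zi: float,
    pi: float,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> str:
    """Map a (Zi, Pi) pair to one of the four node roles.

    network_hub: Zi > 2.5 and Pi > 0.62; module_hub: Zi > 2.5 and Pi <= 0.62;
    connector: Zi <= 2.5 and Pi > 0.62; peripheral otherwise.  Both hub and
    connector inequalities are strict, so (2.5, 0.62) is peripheral.
    """
    high_z = zi > zi_threshold
    high_p = pi > pi_threshold
    if high_z and high_p:
        return "network_hub"
    if high_z:
        return "module_hub"
    if high_p:
        return "connector"
    return "peripheral"


def role_table(
    net: EcoNetwork,
    part: ModulePartition,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """zi_pi augmented with ``role`` and ``is_keystone`` columns."""
    df = zi_pi(net, part)
    df["role"] = [
        classify_role(z, p, zi_threshold, pi_threshold)
        for z, p in zip(df["zi"], df["pi"])
    ]
    df["is_keystone"] = df["role"].isin(KEYSTONE_ROLES)
    return df


def keystone_table(roles: pd.DataFrame, classes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join keystone nodes with their abundance classes.

    ``classes`` is the output of :func:`econet.tables.classify_abundance`.
    Returns (per-OTU table, per-role x class count summary with a
    ``pct_rare`` column).
    """
    keystones = roles[roles["is_keystone"]]
    missing = [o for o in keystones.index if o not in classes.index]
    if missing:
        raise ValueError(f"OTUs missing an abundance class: {missing[:5]}")
    table = keystones[["zi", "pi", "role", "module", "degree"]].copy()
    table["abundance_class"] = classes.loc[table.index, "class"]
    table["mean_abundance"] = classes.loc[table.index, "mean_abundance"]
    if len(table):
        summary = (
            table.groupby(["role", "abundance_class"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        for cls in ("abundant", "rare", "intermediate"):
            if cls not in summary.columns:
                summary[cls] = 0
        totals = summary.sum(axis=1)
        summary["pct_rare"] = 100.0 * summary["rare"] / totals
    else:
        summary = pd.DataFrame(
            columns=["abundant", "rare", "intermediate", "pct_rare"]
        )
    return table, summary


def keystone_diversity_association(
    abundance,
    diversity: pd.DataFrame,
    keystones: pd.DataFrame,
    method: str = "spearman",
    alpha: float = 0.05,
    indices: tuple = ("shannon", "richness"),
) -> pd.DataFrame:
    """Correlate each keystone OTU's abundance with alpha-diversity indices.

    ``abundance`` is an AbundanceTable (samples aligned with ``diversity``'s
    index); ``keystones`` is a role table restricted or not (only rows with
    ``is_keystone`` are screened).  ``passes_all`` is True iff p < ``alpha``
    for every configured index.  OTUs with constant abundance are excluded
    with a ``constant`` flag.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    samples = list(diversity.index)
    data = abundance.data[samples]
    rows = []
    screened = keystones[keystones.get("is_keystone", True)] if "is_keystone" in keystones else keystones
    for otu in screened.index:
        if otu not in data.index:
            continue
        x = data.loc[otu].to_numpy(dtype=float)
        row = {"otu_id": otu, "role": screened.loc[otu, "role"], "constant": False}
        if np.all(x == x[0]):
            row["constant"] = True
            for ind in indices:
                row[f"r_{ind}"] = np.nan
                row[f"p_{ind}"] = np.nan
            row["passes_all"] = False
            rows.append(row)
            continue
        ok = True
        for ind in indices:
            y = diversity[ind].to_numpy(dtype=float)
            r, p = corr(x, y)
            row[f"r_{ind}"] = float(r)
            row[f"p_{ind}"] = float(p)
            ok = ok and (p < alpha)
        row["passes_all"] = bool(ok)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["role", "otu_id"]).set_index("otu_id")
    return out
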