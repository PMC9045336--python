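"""Per-group orchestration, cross-group statistics and reporting.

``run_pipeline`` drives the full analysis for one count table: per-group
(time point or stage) network construction and characterization, then
cross-group trend regressions, ANOVA/LSD comparisons and networked-OTU
overlap counts.  Every seed, threshold and policy lands in a deterministic
JSON manifest.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import netbuild, node_roles, nullmodels, stability, tables, topology
from .netbuild import EcoNetwork

__all__ = [
    "AnalysisConfig",
    "TrendResult",
    "regress_vs_time",
    "anova_lsd",
    "networked_community_overlap",
    "run_pipeline",
]


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs; serialized into the manifest."""

    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    out_dir: str = "econet_out"
    grouping: str = "by_stage"  # or "by_dph"
    min_replicates: int = 27
    st_policy: str = "fixed"  # or "scan"
    st: float = netbuild.DEFAULT_ST
    scan_grid: tuple = netbuild.DEFAULT_SCAN_GRID
    prevalence: float = 0.2
    rarefaction_depth: int | None = None
    filter_before_rarefaction: bool = False
    null_reps: int = nullmodels.DEFAULT_NULL_REPS
    cohesion_reps: int = stability.DEFAULT_COHESION_REPS
    seed: int = 0
    large_module_min_size: int = 5
    association_method: str = "spearman"
    regression_subset: list | None = None  # restrict trend fits to these times

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cfg = cls(**doc)
        if isinstance(cfg.scan_grid, list):
            cfg.scan_grid = tuple(cfg.scan_grid)
        return cfg


@dataclass
class TrendResult:
    metric: str
    slope: float
    adjusted_r2: float
    p: float
    times: list
    values: list


def regress_vs_time(values, times, metric: str = "", subset=None) -> TrendResult:
    """OLS of a per-group metric on time (dph).

    ``subset``: optional collection of time points to restrict the fit to
    (explicit, never automatic).  Requires >= 3 points after subsetting.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if subset is not None:
        mask = np.isin(times, np.asarray(list(subset), dtype=float))
        values, times = values[mask], times[mask]
    if len(values) < 3:
        raise ValueError("need at least 3 points for a trend regression")
    if np.ptp(values) == 0:
        return TrendResult(metric=metric, slope=0.0, adjusted_r2=0.0, p=1.0,
                           times=[float(t) for t in times],
                           values=[float(v) for v in values])
    x = sm.add_constant(times)
    fit = sm.OLS(values, x).fit()
    return TrendResult(
        metric=metric,
        slope=float(fit.params[1]),
        adjusted_r2=float(fit.rsquared_adj),
        p=float(fit.pvalues[1]),
        times=[float(t) for t in times],
        values=[float(v) for v in values],
    )


def anova_lsd(values, groups, alpha: float = 0.05, holm: bool = False) -> dict:
    """One-way ANOVA plus pairwise least-significant-difference t-tests.

    Pairwise tests use the pooled ANOVA mean-square error with N - k degrees
    of freedom (unadjusted by default; ``holm=True`` applies a Holm
    correction).  The compact letter display assigns a letter to each
    maximal clique of the "not significantly different" graph, so two groups
    share a letter iff their pairwise p >= ``alpha``.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    df = df.dropna()
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in levels}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    f_stat, f_p = stats.f_oneway(*[by_group[g] for g in levels])
    n_total = len(df)
    k = len(levels)
    dof = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in by_group.values()) / dof
    degenerate = mse == 0

    pair_p = {}
    for a, b in itertools.combinations(levels, 2):
        va, vb = by_group[a], by_group[b]
        if degenerate:
            p = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            t = (va.mean() - vb.mean()) / np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            p = 2.0 * stats.t.sf(abs(t), dof)
        pair_p[(a, b)] = float(p)
    if holm:
        keys = sorted(pair_p, key=lambda kk: pair_p[kk])
        m = len(keys)
        adj, running = {}, 0.0
        for i, kk in enumerate(keys):
            running = max(running, min(1.0, (m - i) * pair_p[kk]))
            adj[kk] = running
        pair_p = adj

    # letters: one per maximal clique of the non-significance graph
    g = nx.Graph()
    g.add_nodes_from(levels)
    for (a, b), p in pair_p.items():
        if p >= alpha:
            g.add_edge(a, b)
    means = {lv: by_group[lv].mean() for lv in levels}
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(g)),
        key=lambda c: (-max(means[x] for x in c), c),
    )
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for i, clique in enumerate(cliques):
        for lv in clique:
            letters[lv] += alphabet[i % len(alphabet)]
    return {
        "F": float(f_stat),
        "p": float(f_p),
        "dof": int(dof),
        "mse": float(mse),
        "pairwise_p": {f"{a}|{b}": p for (a, b), p in pair_p.items()},
        "letters": letters,
        "degenerate": bool(degenerate),
    }


def networked_community_overlap(nets: dict) -> tuple[pd.DataFrame, dict]:
    """Venn-style counts of OTUs across networks.

    ``nets`` maps label -> EcoNetwork (or a node collection).  Returns a
    region table (one row per nonempty label combination, with the count of
    OTUs exclusive to exactly that combination) and a dict of the member
    lists.  Counts satisfy inclusion-exclusion exactly because regions are
    exclusive.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    sets = {
        label: set(net.nodes) if isinstance(net, EcoNetwork) else set(net)
        for label, net in nets.items()
    }
    labels = list(sets)
    rows, members = [], {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(
                *(sets[c] for c in labels if c not in combo), set()
            ) if len(combo) < len(labels) else set()
            exclusive = inside - outside
            key = "&".join(combo)
            rows.append({"region": key, "n_labels": r, "count": len(exclusive)})
            members[key] = sorted(exclusive, key=str)
    return pd.DataFrame(rows), members


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _group_samples(meta: pd.DataFrame, grouping: str) -> dict:
    key = "stage" if grouping == "by_stage" else "dph"
    if key not in meta.columns:
        raise ValueError(f"metadata lacks a {key!r} column for grouping {grouping!r}")
    out = {}
    for g, sub in meta.groupby(key, sort=True):
        out[g] = list(sub.index)
    return out


def _analyze_group(
    label,
    table: tables.CountTable,
    cfg: AnalysisConfig,
    seed: int,
) -> dict:
    """Full single-network analysis for one sample group."""
    result: dict = {"group": str(label), "n_samples": len(table.sample_ids)}
    filtered = tables.prevalence_filter(table, cfg.prevalence)
    rel = tables.to_relative(filtered)
    log_mat = tables.log_transform(rel)
    sim = netbuild.spearman_matrix(log_mat)
    if cfg.st_policy == "scan":
        scan = netbuild.rmt_threshold_scan(sim, cfg.scan_grid)
        st = scan.chosen_st if scan.chosen_st is not None else cfg.st
        result["scan"] = scan
        result["st_source"] = "scan" if scan.chosen_st is not None else "fixed_fallback"
    else:
        st = cfg.st
        result["st_source"] = "fixed"
    result["st"] = float(st)
    net = netbuild.build_network(sim, st, provenance=str(label))
    result["network"] = net
    if net.n_links == 0:
        warnings.warn(f"group {label!r}: empty network; skipping characterization")
        return result
    part = topology.detect_modules(net, seed=seed)
    result["partition"] = part
    result["summary"] = topology.summarize(net, part)
    result["large_modules"] = topology.large_modules(part, cfg.large_module_min_size)
    result["node_table"] = topology.node_table(net, part, cfg.large_module_min_size)
    metrics = {
        "avg_degree": lambda n: 2.0 * n.n_links / n.n_nodes,
        "modularity": lambda n: topology.detect_modules(n).modularity_q,
        "geodesic_efficiency": topology.geodesic_efficiency,
        "connectedness": topology.connectedness,
        "centralization_stress": (
            topology.centralization_stress if net.n_nodes >= 3 else lambda n: 0.0
        ),
    }
    result["null"] = nullmodels.null_ensemble(net, metrics, cfg.null_reps, seed=seed)
    roles = node_roles.role_table(net, part)
    result["roles"] = roles
    classes = tables.classify_abundance(rel)
    result["abundance_classes"] = classes
    present = [o for o in roles.index if o in classes.index]
    ktab, ksum = node_roles.keystone_table(roles.loc[present], classes)
    result["keystone_table"] = ktab
    result["keystone_summary"] = ksum
    div = tables.alpha_diversity(table)
    result["diversity"] = div
    result["associations"] = node_roles.keystone_diversity_association(
        rel, div, roles, method=cfg.association_method
    )
    coh = stability.cohesion(rel, cfg.cohesion_reps, seed=seed)
    result["cohesion"] = coh
    if net.n_nodes >= 3:
        result["vulnerability"] = stability.vulnerability(net)
    result["negative_link_ratio"] = stability.negative_link_ratio(net)
    return result


def run_pipeline(cfg: AnalysisConfig, table: tables.CountTable | None = None) -> dict:
    """Execute the full per-group + cross-group analysis.

    ``table`` may be supplied directly (e.g. from the synthetic generator);
    otherwise ``cfg.counts_path``/``metadata_path`` are read.  Writes TSV /
    JSON / GraphML outputs under ``cfg.out_dir`` and returns the in-memory
    results dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if table is None:
        if cfg.counts_path is None:
            raise ValueError("either a table or counts_path is required")
        meta = tables.read_metadata(cfg.metadata_path) if cfg.metadata_path else None
        tax = tables.read_taxonomy(cfg.taxonomy_path) if cfg.taxonomy_path else None
        table = tables.read_count_table(cfg.counts_path, metadata=meta, taxonomy=tax)
    if table.metadata is None:
        raise ValueError("pipeline needs sample metadata (dph / stage / tank)")

    rng = np.random.default_rng(cfg.seed)
    seeds = {"rarefaction": int(rng.integers(2**31 - 1))}
    if cfg.filter_before_rarefaction:
        table = tables.prevalence_filter(table, cfg.prevalence)
    if cfg.rarefaction_depth is not None:
        table = tables.rarefy(table, cfg.rarefaction_depth, seed=seeds["rarefaction"])

    diversity = tables.alpha_diversity(table)
    diversity.to_csv(out / "alpha_diversity.tsv", sep="\t")

    groups = _group_samples(table.metadata, cfg.grouping)
    group_results: dict = {}
    excluded = []
    for label, samples in groups.items():
        if len(samples) < cfg.min_replicates:
            excluded.append(str(label))
            continue
        seeds[f"group:{label}"] = int(rng.integers(2**31 - 1))
        sub = table.subset_samples(samples)
        res = _analyze_group(label, sub, cfg, seeds[f"group:{label}"])
        group_results[label] = res
        _write_group_outputs(out, str(label), res)

    report: dict = {
        "groups": group_results,
        "diversity": diversity,
        "excluded_groups": excluded,
    }

    # cross-group statistics
    with_nets = {
        g: r for g, r in group_results.items() if r.get("network") is not None
        and r["network"].n_links > 0
    }
    if len(with_nets) >= 2:
        overlap, members = networked_community_overlap(
            {str(g): r["network"] for g, r in with_nets.items()}
        )
        overlap.to_csv(out / "networked_otu_overlap.tsv", sep="\t", index=False)
        report["overlap"] = overlap
        report["overlap_members"] = members
    if len(with_nets) >= 3 and all("summary" in r for r in with_nets.values()):
        times, trend_rows = [], []
        for g, r in with_nets.items():
            meta = table.metadata.loc[table.metadata.index.isin(groups[g])]
            times.append(float(meta["dph"].mean()))
        for metric in ("n_nodes", "n_links", "avg_degree", "connectedness"):
            vals = [getattr(r["summary"], metric) for r in with_nets.values()]
            try:
                tr = regress_vs_time(vals, times, metric, subset=cfg.regression_subset)
                trend_rows.append(asdict(tr))
            except ValueError:
                pass
        report["trends"] = trend_rows
        with open(out / "trends.json", "w") as fh:
            json.dump(trend_rows, fh, indent=2, sort_keys=True)
    # stability ANOVA across groups (per-sample cohesion values)
    coh_rows = []
    for g, r in group_results.items():
        if "cohesion" not in r:
            continue
        sub = r["cohesion"].samples.copy()
        sub["group"] = str(g)
        coh_rows.append(sub)
    if len(coh_rows) >= 2:
        allcoh = pd.concat(coh_rows)
        allcoh.to_csv(out / "stability_per_sample.tsv", sep="\t")
        report["stability_anova"] = {}
        for col in ("cohesion_pos", "cohesion_neg", "np_ratio"):
            sub = allcoh.dropna(subset=[col])
            counts = sub.groupby("group").size()
            if len(counts) >= 2 and (counts >= 2).all():
                report["stability_anova"][col] = anova_lsd(sub[col], sub["group"])
        with open(out / "stability_anova.json", "w") as fh:
            json.dump(report["stability_anova"], fh, indent=2, sort_keys=True)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "seeds": seeds,
        "groups_analyzed": sorted(str(g) for g in group_results),
        "groups_excluded_from_networks": sorted(excluded),
        "st_used": {str(g): r["st"] for g, r in group_results.items() if "st" in r},
        "policies": {
            "prevalence_boundary": "inclusive (>=)",
            "edge_criterion": "|r| >= st",
            "pseudocount": "half minimum nonzero relative abundance",
            "stress_centralization": "sum(max - s) / ((n - 1) * max)",
            "cohesion_connectedness_denominator": "taxa",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    return report


def _write_group_outputs(out: Path, label: str, res: dict) -> None:
    prefix = out / f"group_{label}"
    prefix.mkdir(exist_ok=True)
    net = res.get("network")
    if net is None or net.n_links == 0:
        return
    net.write_edge_list(prefix / "edges.tsv")
    net.write_graphml(prefix / "network.graphml")
    res["node_table"].to_csv(prefix / "nodes.tsv", sep="\t")
    with open(prefix / "topology.json", "w") as fh:
        json.dump(res["summary"].to_dict(), fh, indent=2, sort_keys=True)
    res["null"].table.to_csv(prefix / "null_summary.tsv", sep="\t")
    res["roles"].to_csv(prefix / "zipi_roles.tsv", sep="\t")
    res["keystone_table"].to_csv(prefix / "keystones.tsv", sep="\t")
    if len(res["associations"]):
        res["associations"].to_csv(prefix / "keystone_associations.tsv", sep="\t")
    res["cohesion"].samples.to_csv(prefix / "cohesion.tsv", sep="\t")
    stability_row = {
        "group": label,
        "negative_link_fraction": res["negative_link_ratio"],
    }
    if "vulnerability" in res:
        stability_row["global_efficiency"] = res["vulnerability"].global_efficiency
        stability_row["network_vulnerability"] = res["vulnerability"].network_vulnerability
    pd.DataFrame([stability_row]).to_csv(
        prefix / "network_stability.tsv", sep="\t", index=False
    )
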