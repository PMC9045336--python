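"""Signed co-occurrence network construction.

Pipeline: Spearman correlation on log-transformed relative abundances,
similarity threshold selection by a random-matrix-theory scan of the
eigenvalue nearest-neighbour spacing distribution (NNSD), and thresholded
graph construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

__all__ = [
    "SimilarityMatrix",
    "EcoNetwork",
    "ThresholdScan",
    "spearman_matrix",
    "rmt_threshold_scan",
    "build_network",
    "powerlaw_fit",
    "DEFAULT_ST",
    "DEFAULT_SCAN_GRID",
]

#: Fixed similarity threshold used when the RMT scan is bypassed.
DEFAULT_ST = 0.802

#: Default (lo, hi, step) grid for the threshold scan.
DEFAULT_SCAN_GRID = (0.30, 0.95, 0.01)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Spearman coefficients between OTUs."""

    otu_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.otu_ids), len(self.otu_ids)):
            raise ValueError("matrix shape does not match otu_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.otu_ids)


@dataclass
class EcoNetwork:
    """Undirected signed weighted graph over OTU nodes.

    Nodes with no edge at the threshold are excluded.  Edge attributes:
    ``weight`` (the correlation) and ``sign`` (+1/-1).
    """

    graph: nx.Graph
    st: float
    provenance: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_negative(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] < 0)

    @property
    def n_positive(self) -> int:
        return self.n_links - self.n_negative

    def skeleton(self) -> nx.Graph:
        """Unweighted, unsigned copy used for all distance-based metrics."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(self.graph.edges)
        return g

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])

    def write_edge_list(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def spearman_matrix(log_abundance: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Spearman correlations between OTUs (rows) across samples.

    Ties get average ranks.  OTUs with zero variance across samples have
    undefined rank correlations; their entries are set to 0 with a warning.
    """
    x = np.asarray(log_abundance, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples for Spearman correlation")
    ranks = stats.rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    flat = sd == 0
    if flat.any():
        ids = [log_abundance.index[i] for i in np.flatnonzero(flat)]
        warnings.warn(
            f"{len(ids)} zero-variance OTU(s) set to 0 correlation: {ids[:5]}...",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(list(log_abundance.index), corr)


# ---------------------------------------------------------------------------
# RMT threshold scan
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Per-threshold NNSD goodness-of-fit record and the chosen threshold."""

    records: pd.DataFrame
    chosen_st: float | None
    poisson_alpha: float = 0.05
    goe_alpha: float = 0.05


def _nnsd_spacings(eigvals: np.ndarray) -> np.ndarray | None:
    """Unfold eigenvalues with a smoothing spline on the cumulative spectral
    function and return normalized nearest-neighbour spacings (mean 1)."""
    eig = np.sort(eigvals)
    # collapse (near-)degenerate eigenvalues: spacings within a degenerate
    # cluster are an artifact of thresholding, not of the spacing law
    keep = np.concatenate(([True], np.diff(eig) > 1e-8))
    eig = eig[keep]
    n = eig.size
    if n < 20:
        return None
    cdf = np.arange(1, n + 1) / n
    try:
        spline = UnivariateSpline(eig, cdf, k=3, s=max(5.0 / n, 1e-4))
        unfolded = n * spline(eig)
    except Exception:
        coeffs = np.polyfit(eig, cdf, deg=min(7, n - 2))
        unfolded = n * np.polyval(coeffs, eig)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < 10:
        return None
    return spacings / spacings.mean()


def _gof_pvalues(spacings: np.ndarray, bin_width: float = 0.1, s_max: float = 3.0):
    """Chi-squared goodness of fit of the NNSD against the Poisson law
    exp(-s) and the GOE Wigner surmise (pi/2) s exp(-pi s^2 / 4)."""
    edges = np.arange(0.0, s_max + bin_width / 2, bin_width)
    obs, _ = np.histogram(spacings, bins=edges)
    obs = np.append(obs, np.sum(spacings >= s_max))  # tail bin
    n = obs.sum()

    def chi2_p(cdf_fn):
        probs = np.diff(cdf_fn(edges))
        probs = np.append(probs, 1.0 - cdf_fn(np.array([s_max]))[0])
        exp = n * probs
        # merge bins with tiny expectation into the tail to keep chi2 valid
        mask = exp >= 1.0
        o = np.append(obs[mask], obs[~mask].sum())
        e = np.append(exp[mask], exp[~mask].sum())
        if e[-1] <= 0:
            o, e = o[:-1], e[:-1]
        chi2 = float(((o - e) ** 2 / e).sum())
        dof = max(len(o) - 1, 1)
        return chi2, float(stats.chi2.sf(chi2, dof))

    poisson_cdf = lambda s: 1.0 - np.exp(-s)
    goe_cdf = lambda s: 1.0 - np.exp(-np.pi * s**2 / 4.0)
    chi2_p_pois, p_pois = chi2_p(poisson_cdf)
    chi2_p_goe, p_goe = chi2_p(goe_cdf)
    return chi2_p_pois, p_pois, chi2_p_goe, p_goe


def rmt_threshold_scan(
    similarity: SimilarityMatrix,
    grid: tuple[float, float, float] = DEFAULT_SCAN_GRID,
    poisson_alpha: float = 0.05,
    goe_alpha: float = 0.05,
) -> ThresholdScan:
    """Scan candidate thresholds and pick the smallest one at which the
    thresholded matrix's NNSD follows Poisson (p > ``poisson_alpha``) while
    the GOE law is rejected (p < ``goe_alpha``).

    Returns a scan whose ``chosen_st`` is ``None`` when no grid point
    satisfies the rule; callers may then fall back to a fixed threshold.
    """
    lo, hi, step = grid
    if not (0 < lo < hi < 1):
        raise ValueError("grid must lie within (0, 1)")
    if similarity.values.shape[0] < 20:
        raise ValueError("need at least 20 OTUs for an eigen-spacing scan")
    thresholds = np.round(np.arange(lo, hi + step / 2, step), 10)
    rows = []
    chosen = None
    for t in thresholds:
        m = similarity.values.copy()
        m[np.abs(m) < t] = 0.0
        np.fill_diagonal(m, 1.0)
        eig = np.linalg.eigvalsh(m)
        spacings = _nnsd_spacings(eig)
        if spacings is None:
            rows.append(
                {"threshold": t, "n_spacings": 0, "poisson_chi2": np.nan,
                 "poisson_p": np.nan, "goe_chi2": np.nan, "goe_p": np.nan,
                 "accepted": False}
            )
            continue
        c_pois, p_pois, c_goe, p_goe = _gof_pvalues(spacings)
        accepted = (p_pois > poisson_alpha) and (p_goe < goe_alpha)
        rows.append(
            {"threshold": t, "n_spacings": len(spacings), "poisson_chi2": c_pois,
             "poisson_p": p_pois, "goe_chi2": c_goe, "goe_p": p_goe,
             "accepted": accepted}
        )
        if accepted and chosen is None:
            chosen = float(t)
    return ThresholdScan(pd.DataFrame(rows), chosen, poisson_alpha, goe_alpha)


def build_network(
    similarity: SimilarityMatrix,
    st: float = DEFAULT_ST,
    provenance: str = "",
) -> EcoNetwork:
    """Build the signed network keeping every pair with ``|r| >= st``.

    OTUs with no retained edge are excluded.  An empty result is returned
    (with a warning), not raised.
    """
    if not (0 < st < 1):
        raise ValueError("st must be in (0, 1)")
    ids = similarity.otu_ids
    m = similarity.values
    g = nx.Graph()
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = np.abs(m[iu, ju]) >= st
    for i, j in zip(iu[keep], ju[keep]):
        r = float(m[i, j])
        g.add_edge(ids[i], ids[j], weight=r, sign=1 if r >= 0 else -1)
    if g.number_of_edges() == 0:
        warnings.warn(f"no edges at st={st}; empty network", stacklevel=2)
    return EcoNetwork(g, st=float(st), provenance=provenance)


def powerlaw_fit(degrees) -> dict:
    """OLS fit of log(frequency) on log(degree) over the degree histogram.

    Returns ``{"r_squared", "exponent", "n_points"}``.  Requires at least 3
    distinct positive degree values.
    """
    degrees = np.asarray(list(degrees), dtype=float)
    degrees = degrees[degrees > 0]
    ks, freqs = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError("need at least 3 distinct degree values for a fit")
    res = stats.linregress(np.log(ks), np.log(freqs))
    return {
        "r_squared": float(res.rvalue**2),
        "exponent": float(res.slope),
        "n_points": int(len(ks)),
    }
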