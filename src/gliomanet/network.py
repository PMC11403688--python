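"""Sparse gene-network estimation and network-based variable selection.

Per glioma type, a sparse Gaussian graphical model is fitted by the
graphical lasso,

    max_Theta  log det(Theta) - tr(S Theta) - rho * ||Theta||_1,

whose nonzero off-diagonal entries define the gene network: theta_ij = 0
means genes i and j are conditionally independent given the rest. At a
strong penalty most genes end up unconnected, which yields a network-based
variable selection; connected genes are then ranked by two hub measures
(weighted degree and partner count), rescaled to percentiles, and genes
above a percentile threshold t form the hub set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

ZERO_TOL = 1e-8  # |theta_ij| above this counts as an edge


@dataclass
class CovarianceMatrix:
    S: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape[0] != self.S.shape[1] or len(self.gene_ids) != self.S.shape[0]:
            raise ValueError("inconsistent covariance dimensions")


@dataclass
class PrecisionEstimate:
    theta: np.ndarray
    gene_ids: list[str]
    rho: float
    converged: bool
    n_iter: int
    penalize_diagonal: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class HubScoreTable:
    """Hub measures over the connected (selected) genes of one network.

    weight: sum_j |theta_ij| over partners (weighted degree);
    count: number of nonzero partners; *_pct: the measures rescaled
    uniformly onto [0, 100]; combined_pct: their mean.
    """

    table: pd.DataFrame

    def hubs(self, t: float = 60.0) -> set[str]:
        return identify_hubs(self, t)


@dataclass
class SetComparison:
    only_a: int
    shared: int
    only_b: int
    pct_only_a: float
    pct_only_b: float


@dataclass
class SelectionResult:
    """Per (scheme, type) gene selections: connected, exclusive, hubs."""

    selected: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    exclusive: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    hubs: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            scheme: {
                gtype: {
                    "selected": sorted(self.selected[scheme][gtype]),
                    "exclusive": sorted(self.exclusive[scheme][gtype]),
                    "hubs": sorted(self.hubs[scheme][gtype]),
                }
                for gtype in self.selected[scheme]
            }
            for scheme in self.selected
        }


def empirical_covariance(X: pd.DataFrame) -> CovarianceMatrix:
    """S = (1/n) Xc' Xc with column-centered Xc (population normalization)."""
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 samples")
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    S = (Xc.T @ Xc) / n
    S = (S + S.T) / 2
    return CovarianceMatrix(S, list(X.columns))


def _lasso_cd(
    V: np.ndarray,
    s12: np.ndarray,
    rho: float,
    beta: np.ndarray,
    tol: float,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Coordinate descent for min 0.5 b'Vb - s12'b + rho*||b||_1."""
    q = V @ beta
    diag = np.diag(V)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for k in range(len(beta)):
            num = s12[k] - q[k] + diag[k] * beta[k]
            new = np.sign(num) * max(abs(num) - rho, 0.0) / diag[k]
            d = new - beta[k]
            if d != 0.0:
                q += V[:, k] * d
                beta[k] = new
                max_delta = max(max_delta, abs(d))
        if max_delta < tol:
            break
    return beta


def glasso_fit(
    S: CovarianceMatrix | np.ndarray,
    rho: float = 0.9,
    gene_ids: list[str] | None = None,
    penalize_diagonal: bool = True,
    tol_scale: float = 1e-5,
    max_iter: int = 500,
) -> PrecisionEstimate:
    """Graphical lasso via block coordinate descent over columns.

    Maximizes log det(Theta) - tr(S Theta) - rho ||Theta||_1 with the L1
    norm over all entries by default (``penalize_diagonal=False`` restricts
    it to off-diagonals, the convention of most software defaults). Each
    column update solves a lasso subproblem on the current working
    covariance W; convergence when the max absolute change of Theta per
    sweep drops below ``tol_scale * mean(|diag S|)``.
    """
    if isinstance(S, CovarianceMatrix):
        gene_ids = S.gene_ids
        S = S.S
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if gene_ids is None:
        gene_ids = [f"V{i + 1}" for i in range(p)]
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")

    diag_offset = rho if penalize_diagonal else 0.0
    if p == 1:
        theta = np.array([[1.0 / (S[0, 0] + diag_offset)]])
        return PrecisionEstimate(theta, gene_ids, rho, True, 0, penalize_diagonal)

    W = S + diag_offset * np.eye(p)
    B = np.zeros((p, p))  # column-wise lasso coefficients, B[j, j] unused
    tol = tol_scale * np.mean(np.abs(np.diag(S)))
    inner_tol = max(tol * 1e-2, 1e-10)
    mask = ~np.eye(p, dtype=bool)
    theta_prev = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for j in range(p):
            idx = np.arange(p) != j
            V = W[np.ix_(idx, idx)]
            beta = _lasso_cd(V, S[idx, j], rho, B[idx, j].copy(), inner_tol)
            B[idx, j] = beta
            w12 = V @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        theta = _reconstruct_theta(W, B)
        if theta_prev is not None and np.max(np.abs(theta - theta_prev)) < tol:
            converged = True
            break
        theta_prev = theta
    if not converged:
        raise RuntimeError(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(KKT residual {kkt_residual(theta, S, rho, penalize_diagonal):.3g})"
        )
    theta = (theta + theta.T) / 2
    return PrecisionEstimate(theta, gene_ids, rho, converged, n_iter, penalize_diagonal)


def _reconstruct_theta(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    theta = np.zeros_like(W)
    for j in range(p):
        idx = np.arange(p) != j
        denom = W[j, j] - W[idx, j] @ B[idx, j]
        theta[j, j] = 1.0 / denom
        theta[idx, j] = -B[idx, j] * theta[j, j]
    return theta


def glasso_objective(theta: np.ndarray, S: np.ndarray, rho: float,
                     penalize_diagonal: bool = True) -> float:
    """The penalized Gaussian log-likelihood being maximized."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    l1 = np.abs(theta).sum() if penalize_diagonal else np.abs(theta[~np.eye(len(theta), dtype=bool)]).sum()
    return float(logdet - np.trace(S @ theta) - rho * l1)


def kkt_residual(theta: np.ndarray, S: np.ndarray, rho: float,
                 penalize_diagonal: bool = True) -> float:
    """Max-norm violation of the stationarity condition inv(Theta)-S = rho*dL1."""
    G = np.linalg.inv(theta) - S
    p = len(theta)
    res = 0.0
    for i in range(p):
        for j in range(p):
            penalized = penalize_diagonal or i != j
            if not penalized:
                res = max(res, abs(G[i, j]))
            elif abs(theta[i, j]) > 1e-12:
                res = max(res, abs(G[i, j] - rho * np.sign(theta[i, j])))
            else:
                res = max(res, max(abs(G[i, j]) - rho, 0.0))
    return res


def select_connected(est: PrecisionEstimate, tol: float = ZERO_TOL) -> set[str]:
    """Genes with at least one nonzero off-diagonal precision entry."""
    off = est.theta.copy()
    np.fill_diagonal(off, 0.0)
    connected = np.abs(off).max(axis=1) > tol
    return {g for g, c in zip(est.gene_ids, connected) if c}


def hub_scores(est: PrecisionEstimate, tol: float = ZERO_TOL) -> HubScoreTable:
    """Weight and count hub measures with percentile rescaling.

    Measures and percentiles are computed over the connected genes only;
    ranking the disconnected zero-measure genes would flatten the
    percentile scale.
    """
    off = est.theta.copy()
    np.fill_diagonal(off, 0.0)
    weight = np.abs(off).sum(axis=1)
    count = (np.abs(off) > tol).sum(axis=1)
    selected = count > 0
    genes = [g for g, s in zip(est.gene_ids, selected) if s]
    table = pd.DataFrame(
        {"weight": weight[selected], "count": count[selected]},
        index=pd.Index(genes, name="gene_id"),
    )
    table["weight_pct"] = percentile_rescale(table["weight"].to_numpy())
    table["count_pct"] = percentile_rescale(table["count"].to_numpy())
    table["combined_pct"] = (table["weight_pct"] + table["count_pct"]) / 2
    return HubScoreTable(table)


def percentile_rescale(values: np.ndarray) -> np.ndarray:
    """Rank-based uniform rescaling of a measure onto [0, 100].

    Ascending ranks (average for ties) r in {1..K} map to
    100 (r - 1)/(K - 1); a single value maps to 100.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values
    if values.size == 1:
        return np.array([100.0])
    r = stats.rankdata(values, method="average")
    return 100.0 * (r - 1) / (values.size - 1)


def identify_hubs(table: HubScoreTable, t: float = 60.0) -> set[str]:
    """Union of the genes above threshold t on either percentile scale."""
    if not 0 <= t <= 100:
        raise ValueError("t must lie in [0, 100]")
    tab = table.table
    keep = (tab["weight_pct"] > t) | (tab["count_pct"] > t)
    return set(tab.index[keep])


def compare_sets(A: set[str], B: set[str]) -> SetComparison:
    """Venn-style comparison: exclusive and shared counts plus relative %."""
    only_a, shared, only_b = len(A - B), len(A & B), len(B - A)
    pct_a = 100.0 * only_a / len(A) if A else 0.0
    pct_b = 100.0 * only_b / len(B) if B else 0.0
    return SetComparison(only_a, shared, only_b, pct_a, pct_b)


def rank_crosscheck(genes: set[str] | list[str], other: HubScoreTable) -> pd.DataFrame:
    """Combined percentile of each gene in the *other* scheme's table.

    Genes absent from the other table are reported as "not selected".
    Bands: top >= 66.7, middle in [33.3, 66.7), low < 33.3.
    """
    rows = []
    for g in sorted(genes):
        if g in other.table.index:
            combined = float(other.table.loc[g, "combined_pct"])
            if combined >= 200 / 3:
                band = "top"
            elif combined >= 100 / 3:
                band = "middle"
            else:
                band = "low"
            rows.append((g, combined, band))
        else:
            rows.append((g, np.nan, "not selected"))
    return pd.DataFrame(rows, columns=["gene_id", "combined_pct", "band"]).set_index("gene_id")


def network_edges(est: PrecisionEstimate, tol: float = ZERO_TOL) -> pd.DataFrame:
    """Upper-triangle nonzero entries as an edge list with weights."""
    rows = []
    p = len(est.gene_ids)
    for i in range(p):
        for j in range(i + 1, p):
            w = est.theta[i, j]
            if abs(w) > tol:
                rows.append((est.gene_ids[i], est.gene_ids[j], w))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "theta"])


def export_network(
    est: PrecisionEstimate,
    outdir: str | Path,
    highlights: dict[str, str] | None = None,
    prefix: str = "network",
) -> dict[str, Path]:
    """Write edge list TSV, annotated node table TSV and a GraphML file.

    ``highlights`` maps gene ids to a category (e.g. exclusive /
    survival-selected / neighbor) used as a node attribute.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    highlights = highlights or {}
    edges = network_edges(est)
    edge_path = outdir / f"{prefix}_edges.tsv"
    edges.to_csv(edge_path, sep="\t", index=False)

    nodes = pd.DataFrame(
        {
            "gene_id": est.gene_ids,
            "category": [highlights.get(g, "none") for g in est.gene_ids],
        }
    )
    node_path = outdir / f"{prefix}_nodes.tsv"
    nodes.to_csv(node_path, sep="\t", index=False)

    G = nx.Graph()
    for g in est.gene_ids:
        G.add_node(g, category=highlights.get(g, "none"))
    for _, row in edges.iterrows():
        G.add_edge(row["gene_a"], row["gene_b"], weight=float(row["theta"]))
    graphml_path = outdir / f"{prefix}.graphml"
    nx.write_graphml(G, graphml_path)
    return {"edges": edge_path, "nodes": node_path, "graphml": graphml_path}
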