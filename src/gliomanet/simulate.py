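"""Synthetic glioma expression, classification-label and survival data.

Emulates the statistical structure the network/survival pipeline assumes:
multivariate-Gaussian expression with block-sparse precision matrices that
differ between the three glioma types (astrocytoma, oligodendroglioma, GBM),
a fraction of non-Gaussian marginals, two partially discordant WHO-style
classification label sets driven by molecular flags (IDH status, 1p/19q
codeletion, histology), and right-censored survival times from a Cox
proportional-hazards model with a sparse true coefficient vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

GLIOMA_TYPES = ("astrocytoma", "oligodendroglioma", "GBM")

IDH_VALUES = ("mutant", "wildtype")
CODEL_VALUES = ("codel", "non-codel")
HISTOLOGY_VALUES = ("astro", "oligo", "gbm-like")

# histology flag value -> 2016-style (histology-driven) diagnosis
_HISTOLOGY_TO_TYPE = {
    "astro": "astrocytoma",
    "oligo": "oligodendroglioma",
    "gbm-like": "GBM",
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic glioma cohort.

    Defaults describe a desk-scale cohort: 150 samples per glioma type,
    120 genes of which 48 sit in 16 fully connected blocks of 3 and the
    rest are conditionally isolated.
    """

    n_per_type: int = 150
    p: int = 120
    block_sizes: list[int] = field(default_factory=lambda: [3] * 16)
    partial_corr: float = 0.45
    n_prognostic: int = 5
    effect_size: float = 0.5
    baseline_rate: float = 0.1
    censor_rate: float = 0.3
    distort_frac: float = 0.2
    discordance_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_type <= 0 or self.p <= 0 or self.n_prognostic < 0:
            raise ValueError("counts must be positive")
        if sum(self.block_sizes) > self.p:
            raise ValueError("block_sizes sum exceeds p")
        if not -1 < self.partial_corr < 1:
            raise ValueError("partial_corr must lie in (-1, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0 <= self.distort_frac <= 1:
            raise ValueError("distort_frac must lie in [0, 1]")
        if not 0 <= self.discordance_frac <= 1:
            raise ValueError("discordance_frac must lie in [0, 1]")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        # every per-type precision matrix must be constructible
        for k in range(len(GLIOMA_TYPES)):
            generate_precision_matrix(
                self.p, self.block_sizes, self.partial_corr,
                active_blocks=_active_blocks(len(self.block_sizes), k),
            )


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    true_precision: dict[str, np.ndarray]
    true_hubs: dict[str, list[str]]
    beta_true: np.ndarray
    labels: pd.DataFrame  # per-sample molecular flags
    gene_ids: list[str]

    def true_covariance(self, glioma_type: str) -> np.ndarray:
        return np.linalg.inv(self.true_precision[glioma_type])


@dataclass
class SyntheticDataset:
    expression: pd.DataFrame  # samples x genes
    clinical: pd.DataFrame    # sample_id, type_2016, type_2021, os_time, os_event, flags
    truth: GroundTruth
    config: SimulationConfig


def _block_slices(block_sizes: list[int]) -> list[slice]:
    out, start = [], 0
    for size in block_sizes:
        out.append(slice(start, start + size))
        start += size
    return out


def _active_blocks(n_blocks: int, type_index: int) -> list[int]:
    """Which blocks carry nonzero partial correlations for a given type.

    Block b's activity pattern cycles through: shared by all three types,
    exclusive to type 0, to type 1, to type 2 — so shared and exclusive
    selection sets are both nontrivial by construction.
    """
    active = []
    for b in range(n_blocks):
        pattern = b % 4
        if pattern == 0 or pattern == type_index + 1:
            active.append(b)
    return active


def generate_precision_matrix(
    p: int,
    block_sizes: list[int],
    partial_corr: float,
    seed: int | None = None,
    active_blocks: list[int] | None = None,
) -> np.ndarray:
    """Build a block-sparse symmetric positive-definite precision matrix.

    Within each active block every off-diagonal entry equals ``partial_corr``
    (so the realized partial correlation is ``-partial_corr``); genes outside
    blocks are conditionally isolated. The construction is deterministic;
    ``seed`` is accepted for interface symmetry with the other generators.

    Raises ``ValueError`` if the construction is not positive definite.
    """
    if sum(block_sizes) > p:
        raise ValueError("blocks must be disjoint and fit within p genes")
    if not -1 < partial_corr < 1:
        raise ValueError("|partial_corr| must be < 1")
    theta = np.eye(p)
    slices = _block_slices(block_sizes)
    if active_blocks is None:
        active_blocks = list(range(len(block_sizes)))
    for b in active_blocks:
        sl = slices[b]
        k = sl.stop - sl.start
        block = np.full((k, k), partial_corr)
        np.fill_diagonal(block, 1.0)
        theta[sl, sl] = block
    eigmin = np.linalg.eigvalsh(theta)[0]
    if eigmin <= 1e-8:
        raise ValueError(
            f"precision matrix not positive definite (min eigenvalue {eigmin:.3g}); "
            "use a smaller |partial_corr|"
        )
    return theta


def generate_truth(config: SimulationConfig) -> GroundTruth:
    """Per-type precision matrices, true block genes and prognostic effects."""
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i + 1:04d}" for i in range(config.p)]
    slices = _block_slices(config.block_sizes)
    precisions: dict[str, np.ndarray] = {}
    hubs: dict[str, list[str]] = {}
    for k, gtype in enumerate(GLIOMA_TYPES):
        active = _active_blocks(len(config.block_sizes), k)
        precisions[gtype] = generate_precision_matrix(
            config.p, config.block_sizes, config.partial_corr, active_blocks=active
        )
        members = sorted({i for b in active for i in range(slices[b].start, slices[b].stop)})
        hubs[gtype] = [gene_ids[i] for i in members]

    beta = np.zeros(config.p)
    block_members = np.arange(sum(config.block_sizes))
    # prognostic genes live among block members so the diagnostic selection
    # step can in principle retain them
    pool = block_members if len(block_members) >= config.n_prognostic else np.arange(config.p)
    chosen = rng.choice(pool, size=config.n_prognostic, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_prognostic)
    beta[chosen] = signs * config.effect_size

    labels = _generate_flags(config, rng)
    return GroundTruth(precisions, hubs, beta, labels, gene_ids)


def _generate_flags(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Molecular flags per sample, consistent with a latent 2021-style type.

    Histology disagrees with the molecular diagnosis for a minority of
    samples (emulating histology-driven 2016 calls that the molecular 2021
    criteria overturn).
    """
    rows = []
    sample_idx = 0
    for gtype in GLIOMA_TYPES:
        for _ in range(config.n_per_type):
            if gtype == "oligodendroglioma":
                idh, codel, hist = "mutant", "codel", "oligo"
            elif gtype == "astrocytoma":
                idh, codel, hist = "mutant", "non-codel", "astro"
            else:
                idh, codel, hist = "wildtype", "non-codel", "gbm-like"
            if rng.random() < 0.3:  # discordant histological reading
                hist = rng.choice([h for h in HISTOLOGY_VALUES if h != hist])
            rows.append((f"S{sample_idx + 1:04d}", idh, codel, hist))
            sample_idx += 1
    return pd.DataFrame(
        rows, columns=["sample_id", "idh_status", "codel_status", "histology"]
    ).set_index("sample_id")


def generate_expression(
    truth: GroundTruth,
    n_per_type: int | dict[str, int],
    distort_frac: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw zero-mean multivariate-normal expression per type.

    A seeded fraction ``distort_frac`` of gene columns is passed through
    exp(x) to create non-Gaussian marginals; the same columns are distorted
    for all samples, and the map is monotone so the nonparanormal transform
    can undo it.
    """
    if isinstance(n_per_type, int):
        n_per_type = {t: n_per_type for t in GLIOMA_TYPES}
    if any(n <= 0 for n in n_per_type.values()):
        raise ValueError("n_per_type entries must be positive")
    rng = np.random.default_rng(seed)
    p = len(truth.gene_ids)
    blocks, labels = [], []
    sample_ids = []
    offset = 0
    for gtype in GLIOMA_TYPES:
        n = n_per_type[gtype]
        cov = truth.true_covariance(gtype)
        chol = np.linalg.cholesky(cov)
        X = rng.standard_normal((n, p)) @ chol.T
        blocks.append(X)
        labels.extend([gtype] * n)
        sample_ids.extend(f"S{offset + i + 1:04d}" for i in range(n))
        offset += n
    X = np.vstack(blocks)
    n_distort = int(round(distort_frac * p))
    distorted = rng.choice(p, size=n_distort, replace=False)
    X[:, distorted] = np.exp(X[:, distorted])
    expr = pd.DataFrame(X, index=sample_ids, columns=truth.gene_ids)
    return expr, pd.Series(labels, index=sample_ids, name="glioma_type")


def classify_2021(flags: pd.DataFrame) -> pd.Series:
    """Molecular (2021-style) diagnosis, deterministic from the flags.

    IDH-mutant with 1p/19q codeletion -> oligodendroglioma; IDH-mutant
    without codeletion -> astrocytoma; IDH-wildtype -> GBM.
    """
    bad_idh = ~flags["idh_status"].isin(IDH_VALUES)
    bad_codel = ~flags["codel_status"].isin(CODEL_VALUES)
    if bad_idh.any() or bad_codel.any():
        raise ValueError("unknown IDH or codeletion flag value")
    out = pd.Series("GBM", index=flags.index, name="type_2021")
    mutant = flags["idh_status"] == "mutant"
    out[mutant & (flags["codel_status"] == "codel")] = "oligodendroglioma"
    out[mutant & (flags["codel_status"] == "non-codel")] = "astrocytoma"
    return out


def generate_labels(
    flags: pd.DataFrame, discordance_frac: float, seed: int
) -> pd.DataFrame:
    """Scheme-A (2016-like) and scheme-B (2021-like) type labels.

    Scheme B is deterministic from the molecular flags. Scheme A equals
    scheme B except for a seeded ``discordance_frac`` of samples whose
    label follows the histology flag instead.
    """
    if not flags["histology"].isin(HISTOLOGY_VALUES).all():
        raise ValueError("unknown histology flag value")
    type_2021 = classify_2021(flags)
    type_2016 = type_2021.copy().rename("type_2016")
    rng = np.random.default_rng(seed)
    n_disc = int(round(discordance_frac * len(flags)))
    if n_disc > 0:
        idx = rng.choice(len(flags), size=n_disc, replace=False)
        hist_labels = flags["histology"].map(_HISTOLOGY_TO_TYPE)
        type_2016.iloc[idx] = hist_labels.iloc[idx]
    return pd.DataFrame({"type_2016": type_2016, "type_2021": type_2021})


def generate_survival(
    X: pd.DataFrame | np.ndarray,
    beta_true: np.ndarray,
    baseline_rate: float,
    censor_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Right-censored survival times from an exponential PH model.

    Event times are exponential with rate ``baseline_rate * exp(X beta)``;
    censoring times are uniform on [0, c] with c solved numerically so the
    expected censoring fraction matches ``censor_rate``.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    Xv = np.asarray(X, dtype=float)
    if Xv.shape[1] != len(beta_true):
        raise ValueError("beta_true length must equal gene count")
    rng = np.random.default_rng(seed)
    rates = baseline_rate * np.exp(Xv @ beta_true)
    n = len(rates)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate <= 0:
        times, events = event_times, np.ones(n, dtype=int)
    else:
        c = _solve_censor_horizon(rates, censor_rate)
        censor_times = rng.uniform(0.0, c, size=n)
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    return pd.DataFrame({"os_time": times, "os_event": events}, index=index)


def _solve_censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Solve for the uniform-censoring horizon c hitting the target fraction.

    With C ~ U[0, c] and T ~ Exp(r), P(censored) = P(C < T)
    = (1 - exp(-rc))/(rc), which decreases monotonically from 1 to 0 in c.
    """

    def expected_censoring(c: float) -> float:
        rc = rates * c
        return float(np.mean((1.0 - np.exp(-rc)) / rc))

    lo, hi = 1e-8, 1.0
    while expected_censoring(hi) > censor_rate:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket censoring horizon")
    return brentq(lambda c: expected_censoring(c) - censor_rate, lo, hi)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full cohort: expression, dual classification labels, survival, truth.

    All randomness derives from ``config.seed``; repeated calls with the
    same config reproduce bit-identical data.
    """
    truth = generate_truth(config)
    expr, _ = generate_expression(
        truth, config.n_per_type, config.distort_frac, seed=config.seed + 1
    )
    labels = generate_labels(truth.labels, config.discordance_frac, seed=config.seed + 2)
    survival = generate_survival(
        expr, truth.beta_true, config.baseline_rate, config.censor_rate,
        seed=config.seed + 3,
    )
    clinical = pd.concat([labels, survival, truth.labels], axis=1)
    clinical.index.name = "sample_id"
    return SyntheticDataset(expr, clinical.reset_index(), truth, config)


# ---------------------------------------------------------------------------
# I/O

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Genes x samples TSV, first column the gene id."""
    expr.T.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV back into samples x genes orientation."""
    X = pd.read_csv(path, sep="\t", index_col=0).T
    X.columns.name = None
    X.index.name = None
    return X


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "gene_ids": truth.gene_ids,
        "true_precision": {t: m.tolist() for t, m in truth.true_precision.items()},
        "true_hubs": truth.true_hubs,
        "beta_true": truth.beta_true.tolist(),
        "labels": truth.labels.reset_index().to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    labels = pd.DataFrame(payload["labels"]).set_index("sample_id")
    return GroundTruth(
        {t: np.asarray(m) for t, m in payload["true_precision"].items()},
        payload["true_hubs"],
        np.asarray(payload["beta_true"]),
        labels,
        payload["gene_ids"],
    )
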