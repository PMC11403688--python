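"""End-to-end orchestration of the two-step glioma analysis.

For each classification scheme (2016-style histology-influenced labels vs
2021-style molecular labels) the workflow is: preprocess expression ->
per-type graphical-lasso networks and hub scoring -> cross-scheme and
cross-type selection comparisons -> three Pan-Glioma survival case datasets
(case 1: all selected genes; case 2: genes exclusively selected by one
type; case 3: hub genes) -> EPV-capped lasso Cox fit, KDE-minimum risk
stratification, Kaplan-Meier curves and log-rank test -> cross-tabulation
of risk groups against glioma types and cross-case stability.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net
from . import preprocess as pre
from . import simulate as sim
from . import survival as surv

logger = logging.getLogger("gliomanet")

SCHEMES = ("2016", "2021")
SCHEME_COLUMNS = {"2016": "type_2016", "2021": "type_2021"}
CASES = (1, 2, 3)

CASE_RULES = {
    1: "union of per-type selected (connected) genes",
    2: "union of per-type exclusively selected genes",
    3: "union of per-type hub genes",
}


@dataclass
class CaseSpec:
    case_id: int
    scheme: str

    def __post_init__(self) -> None:
        if self.case_id not in CASES:
            raise ValueError("case id must be 1, 2 or 3")
        if self.scheme not in SCHEMES:
            raise ValueError("scheme must be '2016' or '2021'")


@dataclass
class StratificationTable:
    """Risk-group x glioma-type cross tabulation with both percentage styles."""

    counts: pd.DataFrame  # index: glioma type, columns: group labels

    @classmethod
    def from_labels(cls, group: pd.Series, types: pd.Series) -> "StratificationTable":
        if not group.index.equals(types.index):
            types = types.reindex(group.index)
            if types.isna().any():
                raise ValueError("type labels do not cover all stratified samples")
        counts = pd.crosstab(types, group)
        return cls(counts)

    @classmethod
    def from_counts(cls, counts: dict[str, dict[str, int]]) -> "StratificationTable":
        """Build from {group: {type: count}} (e.g. a published table)."""
        return cls(pd.DataFrame(counts).fillna(0).astype(int))

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def group_total(self, group: str) -> int:
        return int(self.counts[group].sum()) if group in self.counts else 0

    def group_pct_of_all(self, group: str) -> float:
        return 100.0 * self.group_total(group) / self.n

    def type_pct_of_group(self, group: str, types: str | list[str]) -> float:
        """Percentage of a risk group made up by one or more glioma types."""
        total = self.group_total(group)
        if total == 0:
            return 0.0
        if isinstance(types, str):
            types = [types]
        c = sum(int(self.counts.loc[t, group]) for t in types if t in self.counts.index)
        return 100.0 * c / total

    def to_frame(self) -> pd.DataFrame:
        """Counts with text-style (one decimal) and table-style (integer) %."""
        rows = []
        for group in self.counts.columns:
            total = self.group_total(group)
            for t in self.counts.index:
                c = int(self.counts.loc[t, group])
                pct = self.type_pct_of_group(group, t)
                rows.append((group, t, c, round(pct, 1), round(pct)))
        return pd.DataFrame(
            rows, columns=["group", "glioma_type", "count", "pct_of_group", "pct_int"]
        )


@dataclass
class RunConfig:
    """Parameters of one pipeline run (synthetic or file-based inputs)."""

    sim: sim.SimulationConfig | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    rho: float = 0.25
    hub_t: float = 60.0
    jb_alpha: float = 0.05
    npn_first: bool = True
    penalize_diagonal: bool = True
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    seed: int = 0
    outdir: str = "gliomanet_run"
    schemes: tuple[str, ...] = SCHEMES
    cases: tuple[int, ...] = CASES

    def __post_init__(self) -> None:
        if self.sim is None and (self.expression_path is None or self.clinical_path is None):
            self.sim = sim.SimulationConfig(seed=self.seed)
        if not 0 <= self.hub_t <= 100 or not 0 < self.jb_alpha < 1 or self.rho < 0:
            raise ValueError("parameter out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_cfg = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "sim"})
        if sim_cfg is not None:
            cfg.sim = sim.SimulationConfig(**sim_cfg)
        return cfg


class StageError(RuntimeError):
    """An error raised within a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[stage: {stage}] {original}")
        self.stage = stage
        self.original = original


def build_case_dataset(
    selection: net.SelectionResult, case: CaseSpec, X: pd.DataFrame
) -> pd.DataFrame:
    """Pan-Glioma feature matrix for one survival case.

    Rows are all samples of all three types; columns are the case's
    deduplicated, sorted gene-set union.
    """
    source = {1: selection.selected, 2: selection.exclusive, 3: selection.hubs}[case.case_id]
    per_type = source[case.scheme]
    genes = sorted(set().union(*per_type.values()))
    if not genes:
        raise ValueError(
            f"empty gene set for case {case.case_id} (scheme {case.scheme})"
        )
    return X[genes]


def tabulate_stratification(
    strat: surv.RiskStratification, types: pd.Series
) -> StratificationTable:
    return StratificationTable.from_labels(strat.group, types)


def stability_overlap(strats: dict[int, pd.Series]) -> dict:
    """Cross-case agreement of risk-group assignments.

    For each group label, the fraction of samples assigned that label in
    every case among those ever assigned it; plus the overall fraction of
    samples with an identical label across all cases.
    """
    keys = list(strats)
    base_index = strats[keys[0]].index
    for k in keys[1:]:
        if not strats[k].index.equals(base_index):
            raise ValueError("stratifications cover different sample sets")
    frame = pd.DataFrame({k: strats[k] for k in keys})
    all_same = frame.nunique(axis=1) == 1
    out: dict = {"overall": float(all_same.mean())}
    for label in pd.unique(frame.to_numpy().ravel()):
        ever = (frame == label).any(axis=1)
        always = (frame == label).all(axis=1)
        out[str(label)] = float(always[ever].mean()) if ever.any() else 1.0
    return out


def _selection_stage(
    X: pd.DataFrame,
    clinical: pd.DataFrame,
    config: RunConfig,
    outdir: Path,
) -> tuple[net.SelectionResult, dict, dict]:
    """Per-(scheme, type) glasso fits, hub scoring and network export."""
    selection = net.SelectionResult()
    hub_tables: dict[tuple[str, str], net.HubScoreTable] = {}
    estimates: dict[tuple[str, str], net.PrecisionEstimate] = {}
    clin = clinical.set_index("sample_id")
    for scheme in config.schemes:
        col = SCHEME_COLUMNS[scheme]
        selection.selected[scheme] = {}
        selection.exclusive[scheme] = {}
        selection.hubs[scheme] = {}
        for gtype in sim.GLIOMA_TYPES:
            samples = clin.index[clin[col] == gtype]
            sub = X.loc[X.index.intersection(samples)]
            logger.info("glasso: scheme=%s type=%s n=%d p=%d rho=%g",
                        scheme, gtype, len(sub), X.shape[1], config.rho)
            S = net.empirical_covariance(sub)
            est = net.glasso_fit(S, rho=config.rho,
                                 penalize_diagonal=config.penalize_diagonal)
            estimates[(scheme, gtype)] = est
            selected = net.select_connected(est)
            table = net.hub_scores(est)
            hub_tables[(scheme, gtype)] = table
            selection.selected[scheme][gtype] = selected
            selection.hubs[scheme][gtype] = net.identify_hubs(table, config.hub_t)
            net.export_network(
                est, outdir / "networks", prefix=f"{scheme}_{gtype}"
            )
        for gtype in sim.GLIOMA_TYPES:
            others = set().union(
                *(selection.selected[scheme][t] for t in sim.GLIOMA_TYPES if t != gtype)
            )
            selection.exclusive[scheme][gtype] = (
                selection.selected[scheme][gtype] - others
            )
    return selection, hub_tables, estimates


def _comparison_stage(
    selection: net.SelectionResult,
    hub_tables: dict,
    config: RunConfig,
    outdir: Path,
) -> dict:
    """Venn-style selection comparisons and hub rank cross-checks."""
    comparisons: dict = {"scheme_vs_scheme": {}, "type_vs_type": {}, "rank_crosscheck": {}}
    if set(config.schemes) >= set(SCHEMES):
        for gtype in sim.GLIOMA_TYPES:
            for kind, src in (("selected", selection.selected), ("hubs", selection.hubs)):
                cmp = net.compare_sets(src["2016"][gtype], src["2021"][gtype])
                comparisons["scheme_vs_scheme"][f"{gtype}_{kind}"] = asdict(cmp)
        # hubs exclusive to one scheme, ranked in the other scheme's table
        for this, other in (("2016", "2021"), ("2021", "2016")):
            for gtype in sim.GLIOMA_TYPES:
                exclusive_hubs = selection.hubs[this][gtype] - selection.hubs[other][gtype]
                cc = net.rank_crosscheck(exclusive_hubs, hub_tables[(other, gtype)])
                comparisons["rank_crosscheck"][f"{this}_{gtype}"] = (
                    cc.reset_index().to_dict(orient="records")
                )
    for scheme in config.schemes:
        for a, b in itertools.combinations(sim.GLIOMA_TYPES, 2):
            for kind, src in (("selected", selection.selected), ("hubs", selection.hubs)):
                cmp = net.compare_sets(src[scheme][a], src[scheme][b])
                comparisons["type_vs_type"][f"{scheme}_{a}_vs_{b}_{kind}"] = asdict(cmp)
    (outdir / "comparisons.json").write_text(json.dumps(comparisons, indent=1))
    return comparisons


def _survival_stage(
    scheme: str,
    case_id: int,
    selection: net.SelectionResult,
    X: pd.DataFrame,
    clinical: pd.DataFrame,
    config: RunConfig,
    outdir: Path,
) -> dict:
    clin = clinical.set_index("sample_id").loc[X.index]
    case = CaseSpec(case_id, scheme)
    features = build_case_dataset(selection, case, X)
    data = surv.SurvivalData(
        clin["os_time"].to_numpy(), clin["os_event"].to_numpy(), features
    )
    pmax = surv.compute_pmax(data.n_events)
    path = surv.cox_lasso_path(
        data, n_lambdas=config.n_lambdas, lambda_min_ratio=config.lambda_min_ratio
    )
    model = surv.select_model(path, pmax)
    pi = surv.prognostic_index(features, model)
    threshold = surv.kde_threshold(pi)
    strat = surv.stratify(pi, threshold)
    curves = surv.km_estimate(data, strat.group)
    lr = surv.logrank_test(data, strat.group)
    types = clin[SCHEME_COLUMNS[scheme]]
    table = tabulate_stratification(strat, types)

    tag = f"{scheme}_case{case_id}"
    case_dir = outdir / "survival"
    case_dir.mkdir(parents=True, exist_ok=True)
    (case_dir / f"{tag}_cox_model.json").write_text(json.dumps(model.to_json_dict(), indent=1))
    strat.to_frame().to_csv(case_dir / f"{tag}_stratification.tsv", sep="\t")
    km_frames = []
    for gname, frame in curves.curves.items():
        f = frame.copy()
        f.insert(0, "group", gname)
        km_frames.append(f)
    pd.concat(km_frames).to_csv(case_dir / f"{tag}_km_curves.tsv", sep="\t", index=False)
    table.to_frame().to_csv(case_dir / f"{tag}_stratification_table.tsv", sep="\t", index=False)

    return {
        "case": case_id,
        "scheme": scheme,
        "n_features": features.shape[1],
        "n_events": data.n_events,
        "pmax": pmax,
        "lambda": model.lam,
        "active_set": model.active_set,
        "threshold": threshold,
        "n_HR": int((strat.group == "HR").sum()),
        "n_LR": int((strat.group == "LR").sum()),
        "logrank_statistic": lr.statistic,
        "logrank_p": lr.p_value,
        "stratification_table": table.to_frame().to_dict(orient="records"),
        "_strat_labels": strat.group,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-step workflow; returns the run summary dict.

    All artifacts (tables, networks, models, summary JSON) are written
    under ``config.outdir``. Deterministic given the config seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "parameters": {
            "rho": config.rho, "hub_t": config.hub_t, "jb_alpha": config.jb_alpha,
            "npn_first": config.npn_first, "seed": config.seed,
            "penalize_diagonal": config.penalize_diagonal,
            "schemes": list(config.schemes), "cases": list(config.cases),
        }
    }

    try:
        if config.sim is not None:
            ds = sim.generate_dataset(config.sim)
            X, clinical = ds.expression, ds.clinical
            sim.write_expression(X, outdir / "expression.tsv")
            sim.write_clinical(clinical, outdir / "clinical.tsv")
            sim.write_truth(ds.truth, outdir / "ground_truth.json")
            summary["parameters"]["sim"] = asdict(config.sim)
        else:
            X = sim.read_expression(config.expression_path)
            clinical = sim.read_clinical(config.clinical_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("data", e) from e

    try:
        Xp, report = pre.preprocess(X, alpha=config.jb_alpha, npn_first=config.npn_first)
        report.to_tsv(outdir / "normality_report.tsv")
        summary["preprocessing"] = {
            "n_genes_in": X.shape[1],
            "n_genes_kept": Xp.shape[1],
            "n_samples": len(Xp),
        }
        logger.info("preprocessing kept %d/%d genes", Xp.shape[1], X.shape[1])
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocessing", e) from e

    try:
        selection, hub_tables, _ = _selection_stage(Xp, clinical, config, outdir)
        (outdir / "selection.json").write_text(
            json.dumps(selection.to_json_dict(), indent=1)
        )
        summary["selection"] = {
            scheme: {
                gtype: {
                    "n_selected": len(selection.selected[scheme][gtype]),
                    "n_exclusive": len(selection.exclusive[scheme][gtype]),
                    "n_hubs": len(selection.hubs[scheme][gtype]),
                }
                for gtype in sim.GLIOMA_TYPES
            }
            for scheme in config.schemes
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("network_selection", e) from e

    try:
        summary["comparisons"] = _comparison_stage(selection, hub_tables, config, outdir)
    except Exception as e:  # noqa: BLE001
        raise StageError("comparisons", e) from e

    summary["survival"] = {}
    strat_by_case: dict[str, dict[int, pd.Series]] = {s: {} for s in config.schemes}
    for scheme in config.schemes:
        for case_id in config.cases:
            try:
                res = _survival_stage(
                    scheme, case_id, selection, Xp, clinical, config, outdir
                )
            except Exception as e:  # noqa: BLE001
                raise StageError(f"survival_{scheme}_case{case_id}", e) from e
            strat_by_case[scheme][case_id] = res.pop("_strat_labels")
            summary["survival"][f"{scheme}_case{case_id}"] = res
        if len(strat_by_case[scheme]) > 1:
            summary["survival"][f"{scheme}_stability"] = stability_overlap(
                strat_by_case[scheme]
            )

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def plot_km(curves: surv.SurvivalCurves, path: str | Path, title: str = "") -> None:
    """Minimal Kaplan-Meier step plot (green LR, red HR convention)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"LR": "tab:green", "HR": "tab:red"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, frame in curves.curves.items():
        ax.step(frame["time"], frame["survival"], where="post",
                label=group, color=colors.get(group))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
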