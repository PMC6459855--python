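"""Cohort-level statistics: hub overlap, cross-measure regression, per-node
ANOVA with FDR and Bonferroni post-hoc tests, and intersubject variability.

Per-subject centrality maps are Z-transformed before any cross-measure
comparison (degree counts, path fractions and flux sums live on different
scales).  Group hubs are detected on the mean of the per-subject Z-maps.
Intersubject variability of a node is the coefficient of variation
CV = sigma/mu of its Z-transformed centrality across subjects; nodes whose
across-subject mean is ~0 have an undefined CV and are reported as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .centrality import (
    CentralityMap,
    HubSet,
    BridgeSet,
    betweenness_node,
    degree_centrality,
    detect_hubs,
    edge_criticality,
    physarum_node_centrality,
    z_transform,
)
from .netio import ConnectivityMatrix
from .physarum import PhysarumParams, all_pairs_flux

logger = logging.getLogger(__name__)

MEASURES = ("C_D_node", "C_B_node", "C_P_node")

#: across-subject mean below which a CV is reported as undefined
CV_MEAN_FLOOR = 1e-12


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index |A∩B| / |A∪B| of two hub or bridge sets.

    Accepts :class:`HubSet`/:class:`BridgeSet` or plain sets.  Two empty
    sets overlap vacuously perfectly and return 1 (with a warning).
    """
    sa = set(a.members) if isinstance(a, (HubSet, BridgeSet)) else set(a)
    sb = set(b.members) if isinstance(b, (HubSet, BridgeSet)) else set(b)
    union = sa | sb
    if not union:
        logger.warning("Jaccard of two empty sets: returning 1 (vacuous overlap)")
        return 1.0
    return len(sa & sb) / len(union)


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r2: float
    p: float


def pairwise_regression(x: CentralityMap, y: CentralityMap) -> RegressionResult:
    """OLS of y on x across nodes: slope, intercept, R², two-sided slope p."""
    if x.labels != y.labels:
        raise ValueError("maps must cover identical nodes")
    if x.n < 3:
        raise ValueError("need at least 3 nodes for regression")
    if np.ptp(x.values) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x.values, y.values)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortResult:
    """Per-subject Z-transformed centrality maps plus group summaries.

    ``zmaps[measure]`` has shape ``(n_subjects, n_nodes)``; group means,
    SDs (ddof=1 across subjects) and group hubs are per measure, with hubs
    detected on the group-mean Z-map.
    """

    labels: tuple[str, ...]
    zmaps: dict[str, np.ndarray]
    group_mean: dict[str, CentralityMap] = field(repr=False)
    group_sd: dict[str, np.ndarray] = field(repr=False)
    group_hubs: dict[str, HubSet] = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return next(iter(self.zmaps.values())).shape[0]

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def node_index(self, node: int | str) -> int:
        return node if isinstance(node, int) else self.labels.index(node)


def build_cohort(
    matrices: Sequence[ConnectivityMatrix],
    params: PhysarumParams | None = None,
    length_mapping: str = "inverse",
) -> CohortResult:
    """Compute C_D, C_B and C_P for every subject; Z-transform; summarize."""
    if not matrices:
        raise ValueError("empty cohort")
    labels = matrices[0].labels
    if any(m.labels != labels for m in matrices):
        raise ValueError("all subjects must share the same node set")
    rows: dict[str, list[np.ndarray]] = {m: [] for m in MEASURES}
    for i, m in enumerate(matrices):
        crit = edge_criticality(all_pairs_flux(m, params, length_mapping))
        per = {
            "C_D_node": degree_centrality(m),
            "C_B_node": betweenness_node(m, length_mapping),
            "C_P_node": physarum_node_centrality(crit),
        }
        for name, cmap in per.items():
            rows[name].append(z_transform(cmap).values)
        logger.info("subject %d/%d done", i + 1, len(matrices))
    zmaps = {name: np.vstack(vals) for name, vals in rows.items()}
    group_mean = {
        name: CentralityMap(measure=name, values=z.mean(axis=0), labels=labels, z=True)
        for name, z in zmaps.items()
    }
    group_sd = {name: z.std(axis=0, ddof=1) if z.shape[0] > 1 else np.zeros(z.shape[1])
                for name, z in zmaps.items()}
    group_hubs = {name: detect_hubs(cmap) for name, cmap in group_mean.items()}
    return CohortResult(
        labels=labels, zmaps=zmaps, group_mean=group_mean,
        group_sd=group_sd, group_hubs=group_hubs,
    )


# ---------------------------------------------------------------------------
# ANOVA across measures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaRow:
    """One node's cross-measure comparison (groups = measures)."""

    node: int
    label: str
    F: float
    p: float
    p_fdr: float
    means: dict[str, float]
    sds: dict[str, float]
    posthoc: tuple[tuple[str, str], ...]  # (smaller, larger) significant pairs


def compare_measures_anova(cohort: CohortResult, alpha: float = 0.05) -> list[AnovaRow]:
    """Per-node one-way ANOVA across the three Z-transformed measures.

    Groups are the measures, observations the subjects.  Raw p-values are
    Benjamini–Hochberg FDR-adjusted across nodes; at FDR-significant nodes,
    the three pairwise two-sample t-tests are Bonferroni-corrected (×3) and
    the significant pairs reported ordered by group mean (smaller, larger).
    """
    if cohort.n_subjects < 2:
        raise ValueError("ANOVA needs at least 2 subjects")
    Fs, ps = [], []
    for node in range(cohort.n_nodes):
        groups = [cohort.zmaps[m][:, node] for m in MEASURES]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            F, p = 0.0, 1.0  # identical constant groups
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                F, p = stats.f_oneway(*groups)
            if np.isnan(F):  # zero within-group variance, unequal means
                F, p = np.inf, 0.0
        Fs.append(float(F))
        ps.append(float(p))
    _, p_fdr, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    rows: list[AnovaRow] = []
    for node in range(cohort.n_nodes):
        groups = {m: cohort.zmaps[m][:, node] for m in MEASURES}
        posthoc: list[tuple[str, str]] = []
        if p_fdr[node] < alpha:
            for i in range(len(MEASURES)):
                for j in range(i + 1, len(MEASURES)):
                    a, b = MEASURES[i], MEASURES[j]
                    if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0:
                        continue
                    _, pt = stats.ttest_ind(groups[a], groups[b])
                    if min(float(pt) * 3, 1.0) < alpha:
                        lo, hi = (a, b) if groups[a].mean() < groups[b].mean() else (b, a)
                        posthoc.append((lo, hi))
        rows.append(
            AnovaRow(
                node=node,
                label=cohort.labels[node],
                F=Fs[node],
                p=ps[node],
                p_fdr=float(p_fdr[node]),
                means={m: float(groups[m].mean()) for m in MEASURES},
                sds={m: float(groups[m].std(ddof=1)) for m in MEASURES},
                posthoc=tuple(posthoc),
            )
        )
    return rows


def anova_table(rows: list[AnovaRow]) -> pd.DataFrame:
    """Flatten ANOVA rows into a tidy frame (one row per node)."""
    return pd.DataFrame(
        {
            "node": [r.label for r in rows],
            "F": [r.F for r in rows],
            "p": [r.p for r in rows],
            "p_fdr": [r.p_fdr for r in rows],
            **{
                f"mean_{m}": [r.means[m] for r in rows] for m in MEASURES
            },
            **{
                f"sd_{m}": [r.sds[m] for r in rows] for m in MEASURES
            },
            "posthoc": [
                ";".join(f"{lo}<{hi}" for lo, hi in r.posthoc) for r in rows
            ],
        }
    )


# ---------------------------------------------------------------------------
# intersubject variability
# ---------------------------------------------------------------------------


def coefficient_of_variation(
    cohort: CohortResult, node: int | str, measure: str
) -> float:
    """CV = sigma/mu of one node's Z-transformed centrality across subjects.

    Returns NaN (missing) when the across-subject mean is within
    ``CV_MEAN_FLOOR`` of zero, where the ratio is undefined.
    """
    if cohort.n_subjects < 2:
        raise ValueError("CV needs at least 2 subjects")
    x = cohort.zmaps[measure][:, cohort.node_index(node)]
    mu = x.mean()
    if abs(mu) < CV_MEAN_FLOOR:
        return float("nan")
    return float(x.std(ddof=1) / mu)


def cv_table(cohort: CohortResult, nodes: Sequence[int | str] | None = None) -> pd.DataFrame:
    """CV per node (rows) and measure (columns); NaN marks undefined cells."""
    nodes = list(range(cohort.n_nodes)) if nodes is None else list(nodes)
    data = {
        m: [coefficient_of_variation(cohort, nd, m) for nd in nodes] for m in MEASURES
    }
    return pd.DataFrame(data, index=[cohort.labels[cohort.node_index(nd)] for nd in nodes])


def cv_comparison_test(
    cohort: CohortResult,
    hub_nodes: Sequence[int | str],
    measure_pair: tuple[str, str],
) -> tuple[float, float]:
    """Two-tailed paired-by-node t-test on CV values across hub nodes.

    Nodes where either measure's CV is undefined are dropped; at least two
    usable nodes are required.
    """
    a_name, b_name = measure_pair
    a = np.array([coefficient_of_variation(cohort, nd, a_name) for nd in hub_nodes])
    b = np.array([coefficient_of_variation(cohort, nd, b_name) for nd in hub_nodes])
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 hub nodes with defined CVs for both measures")
    if np.ptp(a[ok] - b[ok]) == 0:
        # zero-variance differences: degenerate paired t
        if a[ok][0] == b[ok][0]:
            return 0.0, 1.0
        return float(np.inf if a[ok][0] > b[ok][0] else -np.inf), 0.0
    t, p = stats.ttest_rel(a[ok], b[ok])
    return float(t), float(p)
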