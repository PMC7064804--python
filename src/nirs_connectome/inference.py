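"""Group inference: edgewise t-tests, the network-based statistic, edge
taxonomy, covariate residualization, and symptom correlation.

The network-based statistic (NBS) controls familywise error over
connectivity edges at the level of connected components: edges passing a
primary two-sample t threshold (p < p_edge, two-tailed) form suprathreshold
subgraphs, and each component's size (edge count) is referred to the null
distribution of the maximum component size under group-label permutation.
Symptom correlations are Pearson correlations between features and
clinical scores after both sides are residualized on age, sex and
education — equivalent to partial correlation controlling those
covariates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .layout_io import ChannelMap

__all__ = [
    "EdgeStatTable",
    "NBSResult",
    "two_sample_t",
    "two_sample_t_from_summary",
    "edgewise_t",
    "nbs",
    "classify_edge",
    "classify_edges",
    "residualize",
    "symptom_correlation",
    "group_difference_table",
]

EDGE_CLASSES = ("homotopic", "intrahemispheric", "heterotopic")


@dataclasses.dataclass
class EdgeStatTable:
    """Per-edge two-sample statistics on Fisher-z values."""

    table: pd.DataFrame  # columns: i, j, t, p, mean_a, mean_b, suprathreshold
    df: int
    p_edge: float
    t_crit: float

    @property
    def suprathreshold(self) -> pd.DataFrame:
        return self.table[self.table["suprathreshold"]]


@dataclasses.dataclass
class NBSResult:
    """Connected components of the suprathreshold graph with permutation p."""

    components: list[np.ndarray]  # each (m, 2) array of 0-based node pairs
    sizes: np.ndarray  # edge counts
    p_values: np.ndarray  # familywise (1+b)/(1+P)
    component_sign: np.ndarray  # +1 group A > B on average, -1 otherwise
    null_max_sizes: np.ndarray  # length P
    n_permutations: int
    p_edge: float
    seed: int
    edge_stats: EdgeStatTable

    @property
    def significant(self) -> list[int]:
        return [int(k) for k in np.flatnonzero(self.p_values < 0.05)]


def two_sample_t(
    sample_a, sample_b, mode: str = "student"
) -> tuple[float, float, float]:
    """Two-sample t-test; Student (pooled variance) by default, Welch by flag.

    Returns (t, two-tailed p, degrees of freedom).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("both samples have zero variance")
    if mode not in ("student", "welch"):
        raise ValueError(f"unknown mode {mode!r}")
    res = st.ttest_ind(a, b, equal_var=(mode == "student"))
    return float(res.statistic), float(res.pvalue), float(res.df)


def two_sample_t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    mode: str = "student",
) -> tuple[float, float, float]:
    """Two-sample t from summary statistics (means, SDs, group sizes).

    Lets published group summaries (e.g. demographic tables) be re-tested
    without the underlying raw scores.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if mode == "student":
        df = n_a + n_b - 2
        sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
        se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    elif mode == "welch":
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if se == 0:
        raise ValueError("zero pooled variance")
    t = (mean_a - mean_b) / se
    p = 2 * st.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def _stack_upper(z_matrices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_subj, N, N) stack -> (E, n_subj) edge matrix plus (i, j) indices."""
    z_matrices = np.asarray(z_matrices, dtype=float)
    n = z_matrices.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return z_matrices[:, iu, ju].T, iu, ju


def _pooled_t_matrix(
    edge_data: np.ndarray, mask_a: np.ndarray
) -> np.ndarray:
    """Pooled-variance t for every edge under one or many group assignments.

    ``edge_data`` is (E, S); ``mask_a`` is (S,) boolean or (S, P) 0/1 for P
    permuted assignments.  Returns (E,) or (E, P).
    """
    m = np.asarray(mask_a, dtype=float)
    squeeze = m.ndim == 1
    if squeeze:
        m = m[:, None]
    s_total = edge_data.shape[1]
    n_a = m.sum(axis=0)
    n_b = s_total - n_a
    sum_all = edge_data.sum(axis=1, keepdims=True)
    sq_all = (edge_data**2).sum(axis=1, keepdims=True)
    sum_a = edge_data @ m
    sq_a = (edge_data**2) @ m
    mean_a = sum_a / n_a
    mean_b = (sum_all - sum_a) / n_b
    ss_a = sq_a - n_a * mean_a**2
    ss_b = (sq_all - sq_a) - n_b * mean_b**2
    df = s_total - 2
    sp2 = (ss_a + ss_b) / df
    se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    t[~np.isfinite(t)] = 0.0
    return t[:, 0] if squeeze else t


def edgewise_t(
    z_group_a: np.ndarray,
    z_group_b: np.ndarray,
    p_edge: float = 0.001,
) -> EdgeStatTable:
    """Independent pooled two-sample t per off-diagonal channel pair.

    Inputs are stacks of per-subject Fisher-z matrices, shape
    (n_subjects, N, N).  Edges with two-tailed p < ``p_edge`` are flagged
    suprathreshold.
    """
    za = np.asarray(z_group_a, dtype=float)
    zb = np.asarray(z_group_b, dtype=float)
    if za.shape[1:] != zb.shape[1:]:
        raise ValueError("group matrices must share channel dimensions")
    if za.shape[0] < 2 or zb.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    ea, iu, ju = _stack_upper(za)
    eb, _, _ = _stack_upper(zb)
    data = np.hstack([ea, eb])
    mask = np.zeros(data.shape[1], dtype=bool)
    mask[: ea.shape[1]] = True
    t = _pooled_t_matrix(data, mask)
    df = data.shape[1] - 2
    p = 2 * st.t.sf(np.abs(t), df)
    t_crit = float(st.t.isf(p_edge / 2, df))
    table = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "t": t,
            "p": p,
            "mean_a": ea.mean(axis=1),
            "mean_b": eb.mean(axis=1),
            "suprathreshold": np.abs(t) > t_crit,
        }
    )
    return EdgeStatTable(table=table, df=df, p_edge=p_edge, t_crit=t_crit)


def _components_from_edges(
    edge_i: np.ndarray, edge_j: np.ndarray
) -> list[np.ndarray]:
    """Connected components (by shared nodes) of an edge list; each is an
    (m, 2) array of edges."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(edge_i.tolist(), edge_j.tolist()):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[tuple[int, int]]] = {}
    for a, b in zip(edge_i.tolist(), edge_j.tolist()):
        groups.setdefault(find(a), []).append((a, b))
    return [np.array(edges, dtype=int) for edges in groups.values()]


def _max_component_size(edge_i: np.ndarray, edge_j: np.ndarray) -> int:
    if edge_i.size == 0:
        return 0
    return max(len(c) for c in _components_from_edges(edge_i, edge_j))


def nbs(
    z_group_a: np.ndarray,
    z_group_b: np.ndarray,
    p_edge: float = 0.001,
    n_permutations: int = 1000,
    seed: int = 0,
) -> NBSResult:
    """Network-based statistic with group-label permutation.

    Observed suprathreshold edges (two-tailed |t| above the p_edge
    threshold) are grouped into node-connected components; each
    component's familywise p is (1 + #{permutation max size >= observed
    size}) / (1 + P).  An empty suprathreshold graph is a valid empty
    result.  Deterministic given (data, seed).
    """
    stats = edgewise_t(z_group_a, z_group_b, p_edge=p_edge)
    tab = stats.table
    supra = tab[tab["suprathreshold"]]
    components = _components_from_edges(
        supra["i"].to_numpy(), supra["j"].to_numpy()
    )
    # Order components by size, largest (most significant candidate) first.
    components.sort(key=len, reverse=True)
    sizes = np.array([len(c) for c in components], dtype=int)
    signs = np.empty(len(components), dtype=int)
    t_lookup = {
        (int(a), int(b)): float(t)
        for a, b, t in zip(tab["i"], tab["j"], tab["t"])
    }
    for k, comp in enumerate(components):
        mean_t = np.mean([t_lookup[(int(a), int(b))] for a, b in comp])
        signs[k] = 1 if mean_t >= 0 else -1

    n_a = np.asarray(z_group_a).shape[0]
    ea, _, _ = _stack_upper(np.asarray(z_group_a, dtype=float))
    eb, _, _ = _stack_upper(np.asarray(z_group_b, dtype=float))
    data = np.hstack([ea, eb])
    s_total = data.shape[1]

    rng = np.random.default_rng(seed)
    labels = np.zeros(s_total, dtype=float)
    labels[:n_a] = 1.0
    perm_masks = rng.permuted(
        np.tile(labels, (n_permutations, 1)), axis=1
    ).T  # (S, P)
    t_perm = _pooled_t_matrix(data, perm_masks)  # (E, P)
    supra_perm = np.abs(t_perm) > stats.t_crit
    iu_all = tab["i"].to_numpy()
    ju_all = tab["j"].to_numpy()
    null_max = np.zeros(n_permutations, dtype=int)
    for p_idx in range(n_permutations):
        hits = np.flatnonzero(supra_perm[:, p_idx])
        if hits.size:
            null_max[p_idx] = _max_component_size(iu_all[hits], ju_all[hits])
    p_values = np.array(
        [
            (1 + int(np.sum(null_max >= s))) / (1 + n_permutations)
            for s in sizes
        ]
    )
    return NBSResult(
        components=components,
        sizes=sizes,
        p_values=p_values,
        component_sign=signs,
        null_max_sizes=null_max,
        n_permutations=n_permutations,
        p_edge=p_edge,
        seed=seed,
        edge_stats=stats,
    )


def classify_edge(
    channel_a: int, channel_b: int, layout: ChannelMap
) -> str:
    """Spatial class of one edge: homotopic, intrahemispheric or heterotopic.

    Homotopic edges join a declared homolog pair (mirror regions across
    hemispheres); intrahemispheric edges stay within one hemisphere;
    heterotopic edges cross hemispheres between non-homologous regions.
    Edges touching a midline channel never cross hemispheres and are
    classed intrahemispheric.
    """
    ia, ib = layout.index_of(channel_a), layout.index_of(channel_b)
    if int(layout.homolog_id[ia]) == channel_b:
        return "homotopic"
    ha, hb = layout.hemisphere[ia], layout.hemisphere[ib]
    if ha == hb or "midline" in (ha, hb):
        return "intrahemispheric"
    return "heterotopic"


def classify_edges(
    edges: np.ndarray, layout: ChannelMap, zero_based: bool = True
) -> pd.DataFrame:
    """Classify an (m, 2) edge array; indices are 0-based node positions by
    default (set ``zero_based=False`` to pass channel ids directly)."""
    rows = []
    for a, b in np.asarray(edges, dtype=int):
        ca = int(layout.channel_id[a]) if zero_based else int(a)
        cb = int(layout.channel_id[b]) if zero_based else int(b)
        rows.append(
            {
                "channel_a": ca,
                "channel_b": cb,
                "edge_class": classify_edge(ca, cb, layout),
            }
        )
    return pd.DataFrame(rows, columns=["channel_a", "channel_b", "edge_class"])


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    cols = []
    for name in ("age_months", "education_years"):
        if name in covariates:
            cols.append(covariates[name].to_numpy(dtype=float))
    if "sex" in covariates:
        sex = covariates["sex"]
        ind = (
            (sex == "male").to_numpy(dtype=float)
            if sex.dtype == object
            else sex.to_numpy(dtype=float)
        )
        # A single-sex cohort makes the indicator collinear with the
        # intercept; drop it rather than fail.
        if np.unique(ind).size > 1:
            cols.append(ind)
    x = np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    return sm.add_constant(x, has_constant="add")


def residualize(values, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of ``values`` regressed on age, sex and education.

    ``values`` may be a vector or an (n_subjects, n_features) matrix.
    Rejects collinear covariates with a condition-number report.
    """
    y = np.asarray(values, dtype=float)
    design = _design_matrix(covariates)
    n, k = design.shape
    if (y.shape[0] if y.ndim else 0) != n:
        raise ValueError("values and covariates have different lengths")
    if n <= k:
        raise ValueError(f"need more than {k} subjects to fit {k} covariates")
    cond = np.linalg.cond(design)
    if cond > 1e8:
        raise ValueError(
            f"collinear covariates: design condition number {cond:.3g}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def symptom_correlation(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each feature with each symptom score.

    Both sides are residualized on the covariates first (equivalent to
    partial correlation controlling age, sex and education); p-values are
    two-tailed and uncorrected, flagged at ``alpha``.
    """
    n = len(features)
    if len(scores) != n or len(covariates) != n:
        raise ValueError("features, scores and covariates must align")
    if n < 4:
        raise ValueError("need at least 4 subjects for correlation")
    f_res = residualize(features.to_numpy(dtype=float), covariates)
    s_res = residualize(scores.to_numpy(dtype=float), covariates)
    rows = []
    for fi, fname in enumerate(features.columns):
        for si, sname in enumerate(scores.columns):
            r, p = st.pearsonr(f_res[:, fi], s_res[:, si])
            rows.append(
                {
                    "feature": fname,
                    "score": sname,
                    "r": float(r),
                    "p": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def group_difference_table(
    values_a: np.ndarray,
    values_b: np.ndarray,
    names: list[str] | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Feature-wise two-sample t table (e.g. nodal efficiencies by group).

    ``correction='fdr_bh'`` applies Benjamini-Hochberg; default is
    uncorrected p < alpha.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ between groups")
    rows = []
    for k in range(a.shape[1]):
        t, p, df = two_sample_t(a[:, k], b[:, k])
        rows.append(
            {
                "feature": names[k] if names else f"f{k}",
                "t": t,
                "p": p,
                "mean_a": float(a[:, k].mean()),
                "mean_b": float(b[:, k].mean()),
            }
        )
    out = pd.DataFrame(rows)
    if correction == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        out["significant"] = multipletests(out["p"], alpha=alpha, method="fdr_bh")[0]
    else:
        out["significant"] = out["p"] < alpha
    return out
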