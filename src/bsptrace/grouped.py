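"""Grouped analysis: gathering samples, clone statuses, statistics, plots.

The grouped stage consumes the per-sample methylation CSVs written by the
individual stage (one folder, filtered by sequence name), renumbers CpG
ordinals over the union of covered sites, and compares methylation between
experimental groups:

* per CpG, per group pair — two-sample t-test (Welch by default);
* per CpG across all groups — Kruskal-Wallis;
* per sample mean over covered CpGs, then pairwise t-tests on those means.

For cloning-BSP experiments the per-clone percentages are first converted
to binary statuses (<= 20% unmethylated, >= 80% methylated, in between
"not available"); a clone with too many partially methylated CpGs
(> 20% by default) is flagged as a potential mix of clones and fully
masked.  The group-level methylation proportion at a CpG is then
methylated / (methylated + unmethylated) clones.

Raw p-values are reported (no multiple-testing correction by default,
Benjamini-Hochberg available as an option) with the usual significance
symbols: * <= 0.05, ** <= 0.01, *** <= 0.001, **** <= 0.0001.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import BsptraceError
from .methylation import CSV_COLUMNS

UNMETHYLATED = "unmethylated"
METHYLATED = "methylated"
NOT_AVAILABLE = "not_available"


@dataclass
class CloneStatusParams:
    """Thresholds for converting clone percentages into statuses."""

    unmethylated_max: float = 20.0
    methylated_min: float = 80.0
    max_partial_fraction: float = 0.20

    def __post_init__(self):
        if not (0 <= self.unmethylated_max < self.methylated_min <= 100):
            raise ValueError("need 0 <= unmethylated_max < methylated_min <= 100")


@dataclass
class PlotParams:
    """Display options for the visualization suite."""

    cpg_labels: str = "coordinates"     # coordinates | numbers | none
    separate_collections: bool = False
    group_order: list[str] | None = None
    sample_order: str = "group"         # group | methylation | cluster


def call_clone_status(meth: float | None,
                      params: CloneStatusParams | None = None) -> str:
    """Binary methylation status of one clone CpG.

    <= unmethylated_max -> unmethylated; >= methylated_min -> methylated;
    strictly in between (partial, considered defective) or missing ->
    not_available.
    """
    params = params or CloneStatusParams()
    if meth is None or (isinstance(meth, float) and np.isnan(meth)):
        return NOT_AVAILABLE
    if meth <= params.unmethylated_max:
        return UNMETHYLATED
    if meth >= params.methylated_min:
        return METHYLATED
    return NOT_AVAILABLE


def flag_mixed_clone(statuses: list[str],
                     params: CloneStatusParams | None = None,
                     meth_values=None) -> list[str]:
    """Mask a clone whose partial-methylation fraction is too high.

    When the fraction of partially methylated CpGs exceeds
    ``max_partial_fraction`` (strict >), the clone is a potential mix of
    clones and every status becomes not_available.  If *meth_values* is
    given, partial CpGs are identified from the raw percentages (so CpGs
    that are not_available because of missing coverage do not count);
    otherwise every not_available status counts as partial.
    """
    params = params or CloneStatusParams()
    if not statuses:
        raise ValueError("empty status list")
    if meth_values is not None:
        n_partial = sum(
            1 for v in meth_values
            if v is not None and not (isinstance(v, float) and np.isnan(v))
            and params.unmethylated_max < v < params.methylated_min)
    else:
        n_partial = sum(1 for s in statuses if s == NOT_AVAILABLE)
    if n_partial / len(statuses) > params.max_partial_fraction:
        return [NOT_AVAILABLE] * len(statuses)
    return list(statuses)


@dataclass
class GroupedDataset:
    """All per-sample tables of one sequence, on a common CpG numbering."""

    sequence_name: str
    data: pd.DataFrame            # long format, one row per sample x CpG
    matrix: pd.DataFrame          # samples x grouped CpG ordinals, meth_mean
    sample_info: pd.DataFrame     # sample_id, collection, group, replicate, type
    coord_of_ordinal: dict[int, int]
    experiment_type: str
    status_matrix: pd.DataFrame | None = None  # cloning only

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_info["group"]))

    def group_samples(self, group: str) -> list[str]:
        info = self.sample_info
        return list(info.loc[info["group"] == group, "sample_id"])


def gather(results_dir, sequence_name: str,
           clone_params: CloneStatusParams | None = None) -> GroupedDataset:
    """Collect every per-sample CSV for *sequence_name* under *results_dir*.

    CpG ordinals are reset over the union of sites covered by at least one
    sample, numbered 1..K in ascending genomic coordinate.
    """
    clone_params = clone_params or CloneStatusParams()
    results_dir = Path(results_dir)
    frames = []
    for path in sorted(results_dir.rglob("*.csv")):
        try:
            df = pd.read_csv(path)
        except Exception:
            continue
        if not set(CSV_COLUMNS).issubset(df.columns):
            continue
        df = df[df["sequence_name"] == sequence_name]
        if len(df):
            frames.append(df[CSV_COLUMNS])
    if not frames:
        raise BsptraceError(
            f"no per-sample methylation CSV for sequence {sequence_name!r} "
            f"under {results_dir}")
    data = pd.concat(frames, ignore_index=True)
    data["sample_id"] = (data["collection"].astype(str) + "_"
                         + data["group"].astype(str) + "_"
                         + data["replicate_or_clone"].astype(str))
    dup = data.duplicated(["sample_id", "c_coordinate"])
    if dup.any():
        raise BsptraceError("duplicate sample identity in results folder")

    covered = sorted(data.loc[data["meth_mean"].notna(), "c_coordinate"].unique())
    if not covered:
        raise BsptraceError("no CpG covered by any sample")
    ordinal_of_coord = {c: i + 1 for i, c in enumerate(covered)}
    data = data[data["c_coordinate"].isin(covered)].copy()
    data["cpg_ordinal"] = data["c_coordinate"].map(ordinal_of_coord)

    matrix = data.pivot(index="sample_id", columns="cpg_ordinal",
                        values="meth_mean").sort_index(axis=1)
    sample_info = (data[["sample_id", "collection", "group",
                         "replicate_or_clone", "experiment_type"]]
                   .drop_duplicates("sample_id").reset_index(drop=True))
    experiment_type = sample_info["experiment_type"].iloc[0]

    status_matrix = None
    if experiment_type == "cloning":
        rows = {}
        for sample_id, row in matrix.iterrows():
            values = [None if pd.isna(v) else float(v) for v in row]
            statuses = [call_clone_status(v, clone_params) for v in values]
            rows[sample_id] = flag_mixed_clone(statuses, clone_params,
                                               meth_values=values)
        status_matrix = pd.DataFrame.from_dict(
            rows, orient="index", columns=matrix.columns).loc[matrix.index]

    return GroupedDataset(
        sequence_name=sequence_name,
        data=data,
        matrix=matrix,
        sample_info=sample_info,
        coord_of_ordinal={v: k for k, v in ordinal_of_coord.items()},
        experiment_type=experiment_type,
        status_matrix=status_matrix,
    )


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def significance_symbol(p: float | None) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    for cutoff, symbol in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p <= cutoff:
            return symbol
    return "ns"


def welch_t_test(a, b, equal_var: bool = False) -> float | None:
    """Two-sample t-test p-value with degenerate-input guards.

    Groups with fewer than two observations are not testable (``None``).
    When both groups have zero variance the t statistic is undefined; equal
    means give p = 1, distinct means are perfectly separated (p = 0).
    """
    a = np.asarray([x for x in a if x is not None and not np.isnan(x)], dtype=float)
    b = np.asarray([x for x in b if x is not None and not np.isnan(x)], dtype=float)
    if len(a) < 2 or len(b) < 2:
        return None
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)


def kruskal_test(groups) -> float | None:
    """Kruskal-Wallis p-value across groups; ``None`` when untestable."""
    clean = []
    for g in groups:
        g = np.asarray([x for x in g if x is not None and not np.isnan(x)],
                       dtype=float)
        if len(g) >= 2:
            clean.append(g)
    if len(clean) < 2:
        return None
    if all(np.var(g) == 0 for g in clean) and len({g[0] for g in clean}) == 1:
        return 1.0
    try:
        return float(sps.kruskal(*clean).pvalue)
    except ValueError:  # all values identical
        return 1.0


def _bh_adjust(pvalues: pd.Series) -> pd.Series:
    mask = pvalues.notna()
    p = pvalues[mask].to_numpy()
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    out = pvalues.copy()
    out[mask] = adj
    return out


def group_statistics(ds: GroupedDataset, equal_var: bool = False,
                     bh_correction: bool = False) -> dict:
    """Group-comparison statistics bundle.

    Observations are the per-sample ``meth_mean`` values (for cloning
    experiments the masked status matrix is converted back to 0/100 per
    clone).  Returns per-CpG pairwise t-tests, per-CpG Kruskal-Wallis
    tests, per-sample means over covered CpGs, pairwise t-tests on those
    means, and (cloning) per-group methylation proportions.
    """
    matrix = observation_matrix(ds)
    groups = ds.groups
    pairs = list(itertools.combinations(groups, 2))

    pairwise_rows = []
    kruskal_rows = []
    for ordinal in matrix.columns:
        by_group = {g: matrix.loc[matrix.index.isin(ds.group_samples(g)), ordinal]
                    for g in groups}
        for g1, g2 in pairs:
            p = welch_t_test(by_group[g1], by_group[g2], equal_var=equal_var)
            pairwise_rows.append({
                "cpg_ordinal": ordinal,
                "c_coordinate": ds.coord_of_ordinal[ordinal],
                "group1": g1, "group2": g2, "p_value": p,
            })
        p = kruskal_test([by_group[g] for g in groups])
        kruskal_rows.append({
            "cpg_ordinal": ordinal,
            "c_coordinate": ds.coord_of_ordinal[ordinal],
            "p_value": p,
        })

    sample_means = matrix.mean(axis=1, skipna=True)
    means_rows = []
    for g1, g2 in pairs:
        p = welch_t_test(sample_means[sample_means.index.isin(ds.group_samples(g1))],
                         sample_means[sample_means.index.isin(ds.group_samples(g2))],
                         equal_var=equal_var)
        means_rows.append({"group1": g1, "group2": g2, "p_value": p})

    pairwise = pd.DataFrame(pairwise_rows)
    kruskal = pd.DataFrame(kruskal_rows)
    means = pd.DataFrame(means_rows)
    if bh_correction:
        for df in (pairwise, kruskal, means):
            if len(df):
                df["p_value"] = _bh_adjust(df["p_value"])
    for df in (pairwise, kruskal, means):
        if len(df):
            df["symbol"] = df["p_value"].map(significance_symbol)

    group_mean = pd.DataFrame({
        g: matrix.loc[matrix.index.isin(ds.group_samples(g))].mean(skipna=True)
        for g in groups
    })

    result = {
        "per_cpg_pairwise": pairwise,
        "per_cpg_kruskal": kruskal,
        "sample_means": sample_means,
        "means_pairwise": means,
        "group_mean": group_mean,
    }
    if ds.experiment_type == "cloning":
        result["group_proportion"] = clone_group_proportions(ds)
    return result


def observation_matrix(ds: GroupedDataset) -> pd.DataFrame:
    """Per-sample observations used by the statistics layer.

    Direct-BSP: the meth_mean matrix as measured.  Cloning-BSP: statuses
    (after mixed-clone masking) mapped to 0/100, not_available -> NaN.
    """
    if ds.experiment_type != "cloning" or ds.status_matrix is None:
        return ds.matrix
    mapping = {UNMETHYLATED: 0.0, METHYLATED: 100.0, NOT_AVAILABLE: np.nan}
    return ds.status_matrix.replace(mapping).astype(float)


def clone_group_proportions(ds: GroupedDataset) -> pd.DataFrame:
    """Per-CpG methylated-clone proportion per group (percent).

    Proportion = methylated / (methylated + unmethylated); not_available
    clones are excluded from both numerator and denominator.
    """
    if ds.status_matrix is None:
        raise BsptraceError("clone proportions require a cloning dataset")
    out = {}
    for g in ds.groups:
        sub = ds.status_matrix.loc[
            ds.status_matrix.index.isin(ds.group_samples(g))]
        n_meth = (sub == METHYLATED).sum()
        n_unmeth = (sub == UNMETHYLATED).sum()
        denom = (n_meth + n_unmeth).astype(float)
        with np.errstate(invalid="ignore"):
            out[g] = 100.0 * n_meth / denom.where(denom > 0)
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# plots
# --------------------------------------------------------------------------

def _ordered_samples(ds: GroupedDataset, matrix: pd.DataFrame,
                     params: PlotParams) -> list[str]:
    info = ds.sample_info.set_index("sample_id")
    groups = params.group_order or ds.groups
    if params.sample_order == "methylation":
        means = matrix.mean(axis=1, skipna=True).sort_values(ascending=False)
        return list(means.index)
    if params.sample_order == "cluster":
        from scipy.cluster import hierarchy
        filled = matrix.to_numpy(dtype=float)
        col_mean = np.nanmean(filled, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(filled))
        filled[idx] = col_mean[idx[1]]
        if len(matrix) > 2:
            link = hierarchy.linkage(filled, method="average", metric="euclidean")
            order = hierarchy.leaves_list(link)
            return list(matrix.index[order])
        return list(matrix.index)
    # by group (input order or explicit group_order)
    ordered = []
    for g in groups:
        ordered.extend(s for s in matrix.index if info.loc[s, "group"] == g)
    return ordered


def _cpg_x_positions(ds: GroupedDataset) -> dict[int, float]:
    """X positions proportional to genomic coordinates, normalized to [0,1]."""
    coords = ds.coord_of_ordinal
    lo = min(coords.values())
    hi = max(coords.values())
    span = max(hi - lo, 1)
    return {k: (c - lo) / span for k, c in coords.items()}


def _cpg_labels(ds: GroupedDataset, params: PlotParams) -> list[str]:
    if params.cpg_labels == "coordinates":
        return [str(ds.coord_of_ordinal[k]) for k in sorted(ds.coord_of_ordinal)]
    if params.cpg_labels == "numbers":
        return [str(k) for k in sorted(ds.coord_of_ordinal)]
    return ["" for _ in ds.coord_of_ordinal]


def render_plots(ds: GroupedDataset, stats: dict,
                 params: PlotParams | None = None, outdir=".") -> dict[str, Path]:
    """Render the visualization suite to figure files.

    Produces the all-samples lollipop plot, the group-mean lollipop plot,
    the per-group methylation profile with Kruskal-Wallis symbols, the
    boxplot panel (per-CpG and all-CpG means, with t-test symbols) and the
    genomic heatmap.  With ``separate_collections`` one set of figures is
    rendered per collection.
    """
    params = params or PlotParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if params.separate_collections and ds.sample_info["collection"].nunique() > 1:
        outputs = {}
        for collection in ds.sample_info["collection"].unique():
            keep = ds.sample_info.loc[
                ds.sample_info["collection"] == collection, "sample_id"]
            sub = GroupedDataset(
                sequence_name=ds.sequence_name,
                data=ds.data[ds.data["sample_id"].isin(keep)],
                matrix=ds.matrix.loc[ds.matrix.index.isin(keep)],
                sample_info=ds.sample_info[
                    ds.sample_info["sample_id"].isin(keep)].reset_index(drop=True),
                coord_of_ordinal=ds.coord_of_ordinal,
                experiment_type=ds.experiment_type,
                status_matrix=(ds.status_matrix.loc[
                    ds.status_matrix.index.isin(keep)]
                    if ds.status_matrix is not None else None),
            )
            sub_stats = group_statistics(sub)
            sub_params = PlotParams(cpg_labels=params.cpg_labels,
                                    separate_collections=False,
                                    group_order=params.group_order,
                                    sample_order=params.sample_order)
            got = render_plots(sub, sub_stats, sub_params,
                               outdir / str(collection))
            outputs.update({f"{collection}/{k}": v for k, v in got.items()})
        return outputs

    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    matrix = observation_matrix(ds)
    xpos = _cpg_x_positions(ds)
    ordinals = sorted(xpos)
    labels = _cpg_labels(ds, params)
    groups = params.group_order or ds.groups
    prefix = ds.sequence_name
    outputs: dict[str, Path] = {}

    def lollipop(ax, rows: pd.DataFrame, row_names):
        for yi, name in enumerate(row_names):
            ax.hlines(yi, -0.02, 1.02, color="0.85", lw=1, zorder=1)
            for k in ordinals:
                v = rows.loc[name, k] if name in rows.index else np.nan
                x = xpos[k]
                if pd.isna(v):
                    ax.scatter([x], [yi], marker="x", color="0.55", s=36, zorder=3)
                else:
                    ax.scatter([x], [yi], s=110, c=[v], cmap="Greys",
                               vmin=0, vmax=100, edgecolors="black",
                               linewidths=0.8, zorder=3)
        ax.set_yticks(range(len(row_names)), row_names, fontsize=8)
        ax.set_xticks([xpos[k] for k in ordinals], labels,
                      rotation=90, fontsize=7)
        ax.set_xlim(-0.05, 1.05)
        ax.invert_yaxis()

    # (1) all-samples lollipop
    order = _ordered_samples(ds, matrix, params)
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(ordinals)),
                                    1.2 + 0.32 * len(order)))
    lollipop(ax, matrix, order)
    ax.set_title(f"{prefix}: CpG methylation per sample", fontsize=10)
    path = outdir / f"{prefix}_lollipop_samples.png"
    fig.tight_layout(); fig.savefig(path, dpi=110); plt.close(fig)
    outputs["lollipop_samples"] = path

    # (2) group-mean lollipop
    gm = stats["group_mean"].T  # groups x ordinals
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(ordinals)),
                                    1.2 + 0.4 * len(groups)))
    lollipop(ax, gm, [g for g in groups if g in gm.index])
    ax.set_title(f"{prefix}: mean CpG methylation per group", fontsize=10)
    path = outdir / f"{prefix}_lollipop_groups.png"
    fig.tight_layout(); fig.savefig(path, dpi=110); plt.close(fig)
    outputs["lollipop_groups"] = path

    # (3) profile plot with Kruskal-Wallis symbols
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(ordinals)), 4))
    for g in groups:
        if g in gm.index:
            ax.plot([xpos[k] for k in ordinals],
                    [gm.loc[g, k] for k in ordinals],
                    marker="o", label=g)
    kw = stats["per_cpg_kruskal"].set_index("cpg_ordinal")
    for k in ordinals:
        sym = kw.loc[k, "symbol"] if k in kw.index else ""
        if sym and sym != "ns":
            ax.text(xpos[k], 103, sym, ha="center", fontsize=8)
    ax.set_ylim(-5, 112)
    ax.set_ylabel("methylation (%)")
    ax.set_xticks([xpos[k] for k in ordinals], labels, rotation=90, fontsize=7)
    ax.legend(fontsize=8)
    ax.set_title(f"{prefix}: methylation profile (Kruskal-Wallis)", fontsize=10)
    path = outdir / f"{prefix}_profile.png"
    fig.tight_layout(); fig.savefig(path, dpi=110); plt.close(fig)
    outputs["profile"] = path

    # (4) boxplots: per-CpG panels + all-CpG means
    n_panels = len(ordinals) + 1
    ncols = min(6, n_panels)
    nrows = int(np.ceil(n_panels / ncols))
    fig, axes = plt.subplots(nrows, ncols,
                             figsize=(2.1 * ncols, 2.6 * nrows), squeeze=False)
    flat = axes.ravel()
    pw = stats["per_cpg_pairwise"]
    for i, k in enumerate(ordinals):
        ax = flat[i]
        values = [matrix.loc[matrix.index.isin(ds.group_samples(g)), k].dropna()
                  for g in groups]
        ax.boxplot([v if len(v) else [np.nan] for v in values],
                   tick_labels=groups)
        sub = pw[(pw["cpg_ordinal"] == k) & pw["symbol"].isin(
            ["*", "**", "***", "****"])]
        if len(sub):
            ax.set_xlabel(" ".join(
                f"{r.group1}-{r.group2}:{r.symbol}" for r in sub.itertuples()),
                fontsize=6)
        ax.set_title(f"CpG #{k}", fontsize=8)
        ax.tick_params(labelsize=7)
        ax.set_ylim(-5, 105)
    ax = flat[len(ordinals)]
    sm = stats["sample_means"]
    values = [sm[sm.index.isin(ds.group_samples(g))].dropna() for g in groups]
    ax.boxplot([v if len(v) else [np.nan] for v in values], tick_labels=groups)
    mp = stats["means_pairwise"]
    sig = mp[mp["symbol"].isin(["*", "**", "***", "****"])]
    if len(sig):
        ax.set_xlabel(" ".join(
            f"{r.group1}-{r.group2}:{r.symbol}" for r in sig.itertuples()),
            fontsize=6)
    ax.set_title("all-CpG means", fontsize=8)
    ax.tick_params(labelsize=7)
    for j in range(n_panels, len(flat)):
        flat[j].axis("off")
    fig.suptitle(f"{prefix}: methylation by group (t-tests)", fontsize=10)
    path = outdir / f"{prefix}_boxplots.png"
    fig.tight_layout(); fig.savefig(path, dpi=110); plt.close(fig)
    outputs["boxplots"] = path

    # (5) genomic heatmap
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(ordinals)),
                                    1.2 + 0.3 * len(order)))
    arr = matrix.loc[order, ordinals].to_numpy(dtype=float)
    im = ax.imshow(arr, aspect="auto", cmap="Greys", vmin=0, vmax=100,
                   interpolation="nearest")
    ax.set_yticks(range(len(order)), order, fontsize=8)
    ax.set_xticks(range(len(ordinals)), labels, rotation=90, fontsize=7)
    fig.colorbar(im, ax=ax, label="methylation (%)")
    ax.set_title(f"{prefix}: methylation heatmap along the sequence", fontsize=10)
    path = outdir / f"{prefix}_heatmap.png"
    fig.tight_layout(); fig.savefig(path, dpi=110); plt.close(fig)
    outputs["heatmap"] = path
    return outputs


def write_outputs(ds: GroupedDataset, stats: dict, outdir) -> dict[str, Path]:
    """Write the statistics CSVs and the machine-readable JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = ds.sequence_name
    paths = {}
    for name, obj in (("pairwise_t", stats["per_cpg_pairwise"]),
                      ("kruskal", stats["per_cpg_kruskal"]),
                      ("means_pairwise", stats["means_pairwise"])):
        p = outdir / f"{prefix}_stats_{name}.csv"
        obj.to_csv(p, index=False)
        paths[name] = p
    gm = stats["group_mean"].copy()
    gm.insert(0, "c_coordinate",
              [ds.coord_of_ordinal[k] for k in gm.index])
    p = outdir / f"{prefix}_group_means.csv"
    gm.to_csv(p, index_label="cpg_ordinal")
    paths["group_means"] = p

    summary = {
        "sequence_name": ds.sequence_name,
        "experiment_type": ds.experiment_type,
        "n_samples": int(len(ds.matrix)),
        "groups": ds.groups,
        "n_cpg": int(len(ds.coord_of_ordinal)),
        "cpg_coordinates": {str(k): int(v)
                            for k, v in ds.coord_of_ordinal.items()},
        "sample_means": {k: (None if pd.isna(v) else round(float(v), 2))
                         for k, v in stats["sample_means"].items()},
        "kruskal_p": {str(r.cpg_ordinal):
                      (None if pd.isna(r.p_value) else float(r.p_value))
                      for r in stats["per_cpg_kruskal"].itertuples()},
    }
    p = outdir / f"{prefix}_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    paths["summary"] = p
    return paths
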