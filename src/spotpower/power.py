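"""Bootstrap power estimation for two-group differential expression.

Given a preliminary two-condition Visium dataset and an ROI, the estimator:

1. draws pseudo-experiments by resampling ROI spots with replacement,
   ``n_spots * N`` spots per condition (``N`` slices of ``n_spots`` spots);
2. log-normalizes each pseudo-experiment and runs a Seurat
   ``FindMarkers``-style Wilcoxon rank-sum DE analysis with Bonferroni
   correction over all genes;
3. repeats B times and reports, per gene, the fraction of repetitions in
   which the adjusted p-value fell below the desired level alpha:

       power_g = (1/B) * sum_i 1{ p_adj(g, i) < alpha }.

A repetition in which a gene failed the detection/fold-change prefilter
counts as non-significant, while the reported detection rate pi_g and
effect size |beta_g| are averaged over the repetitions where the gene was
actually evaluated.  The resulting (pi_g, |beta_g|, N, power) rows are the
training points for the power-surface fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .dataio import ROISelection, SpotDataset, ValidationError

__all__ = [
    "BootstrapSpec",
    "DEOptions",
    "bootstrap_replicates",
    "lognormalize",
    "wilcoxon_de",
    "power_from_adjusted_pvalues",
    "estimate_power",
    "power_vs_null_check",
]

#: Columns of the DE result table (one row per gene = one DEGeneResult).
DE_COLUMNS = ["gene", "p_value", "p_adj", "avg_logfc", "pct1", "pct2", "tested"]

#: Columns of the power table (one row per gene = one PowerRecord).
POWER_COLUMNS = ["gene", "pi_g", "abs_beta_g", "N", "power", "B", "alpha"]


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling design: spots per slice, slices per group, repetitions.

    ``n_spots`` and ``N`` may be single ints (balanced design) or
    ``(group1, group2)`` pairs for imbalanced designs.  ``B`` is the number
    of bootstrap repetitions and ``alpha`` the desired adjusted p-value.
    """

    n_spots: int | tuple[int, int]
    N: int | tuple[int, int]
    B: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_spots", "N"):
            v = getattr(self, name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(int(x) < 1 for x in vals):
                raise ValidationError(f"{name} must be >= 1")
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")

    def group_sizes(self) -> tuple[int, int]:
        """Total resampled spots per group: n_spots * N (per group)."""
        n = self.n_spots if isinstance(self.n_spots, tuple) else (self.n_spots,) * 2
        N = self.N if isinstance(self.N, tuple) else (self.N,) * 2
        return int(n[0]) * int(N[0]), int(n[1]) * int(N[1])

    @property
    def N_label(self) -> int:
        """Scalar N used to tag power records (group-1 value if imbalanced)."""
        return int(self.N[0]) if isinstance(self.N, tuple) else int(self.N)


@dataclass(frozen=True)
class DEOptions:
    """FindMarkers-style options for the Wilcoxon DE stage.

    Defaults follow Seurat: a gene is tested only if detected in at least
    ``min_pct`` of the spots of one group and its average log2 fold change
    exceeds ``logfc_threshold``; p-values are Bonferroni-corrected by the
    total number of genes in the dataset (not just the tested ones).
    """

    min_pct: float = 0.1
    logfc_threshold: float = 0.25
    n_genes_total: int | None = None  # default: all genes in the dataset


def _rep_rng(seed: int, repetition: int) -> np.random.Generator:
    # counter-based substreams: each repetition reproducible on its own
    return np.random.default_rng(np.random.SeedSequence([seed, repetition]))


def bootstrap_replicates(
    sel: ROISelection,
    ds: SpotDataset,
    spec: BootstrapSpec,
    repetition: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Spot indices of one bootstrap pseudo-experiment, one array per group.

    Each group's indices are drawn uniformly with replacement from that
    condition's ROI pool; the stream is a deterministic function of
    ``(spec.seed, repetition)``, independent of execution order.
    """
    rng = _rep_rng(spec.seed, repetition)
    sizes = spec.group_sizes()
    out = []
    for (cond, pool), m in zip(sel.spots_per_condition.items(), sizes):
        pool = np.asarray(pool)
        if pool.size == 0:
            raise ValidationError(f"empty spot pool for condition {cond!r}")
        out.append(pool[rng.integers(0, pool.size, size=m)])
    return out[0], out[1]


def lognormalize(counts: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Seurat LogNormalize: ``ln(1 + 1e4 * count / spot_library_size)``.

    ``counts`` is genes x spots; library sizes are the column sums of the
    given submatrix.  Spots with zero total counts are an error (they carry
    no information and would divide by zero).
    """
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    bad = np.flatnonzero(lib <= 0)
    if bad.size:
        raise ValidationError(
            f"spots with zero library size at columns: {bad[:10].tolist()}"
        )
    return np.log1p(1e4 * counts / lib)


def _logfc(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Seurat average log2 fold change from log-normalized data."""
    ma = np.expm1(xa).mean(axis=1)
    mb = np.expm1(xb).mean(axis=1)
    return np.log2((ma + 1.0) / (mb + 1.0))


def wilcoxon_de(
    groupA: np.ndarray,
    groupB: np.ndarray,
    n_genes_total: int,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """FindMarkers-style Wilcoxon rank-sum DE between two spot groups.

    ``groupA``/``groupB`` are log-normalized genes x spots matrices sharing
    the gene index.  Detection fractions ``pct1``/``pct2`` are the fraction
    of spots with nonzero expression; ``avg_logfc`` is
    ``log2((mean(expm1 xA) + 1) / (mean(expm1 xB) + 1))``.  A gene is tested
    iff ``max(pct1, pct2) >= min_pct`` and ``|avg_logfc| >= logfc_threshold``.
    Tested genes get a two-sided rank-sum p-value (exact for small tie-free
    groups, otherwise the normal approximation with tie and continuity
    corrections, as in R's ``wilcox.test``) and
    ``p_adj = min(1, p * n_genes_total)``.  Untested genes keep NaN p-values
    and ``tested=False``; genes constant across both groups get p = 1.

    Returns a DataFrame with columns ``gene, p_value, p_adj, avg_logfc,
    pct1, pct2, tested`` — one row per gene.
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValidationError("groups must share the gene index")
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise ValidationError("both groups need at least one spot")
    G = A.shape[0]
    pct1 = (A > 0).mean(axis=1)
    pct2 = (B > 0).mean(axis=1)
    lfc = _logfc(A, B)
    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= logfc_threshold)

    pvals = np.full(G, np.nan)
    idx = np.flatnonzero(tested)
    if idx.size:
        sub_a, sub_b = A[idx], B[idx]
        const = (
            (np.ptp(sub_a, axis=1) == 0)
            & (np.ptp(sub_b, axis=1) == 0)
            & (sub_a[:, 0] == sub_b[:, 0])
        )
        var_rows = np.flatnonzero(~const)
        p_sub = np.ones(idx.size)
        if var_rows.size:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = scipy.stats.mannwhitneyu(
                    sub_a[var_rows],
                    sub_b[var_rows],
                    axis=1,
                    alternative="two-sided",
                    use_continuity=True,
                    method="auto",
                )
            p_sub[var_rows] = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)
        pvals[idx] = p_sub
    padj = np.minimum(1.0, pvals * n_genes_total)

    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(G)]
    return pd.DataFrame(
        {
            "gene": np.asarray(gene_ids, dtype=object),
            "p_value": pvals,
            "p_adj": padj,
            "avg_logfc": lfc,
            "pct1": pct1,
            "pct2": pct2,
            "tested": tested,
        },
        columns=DE_COLUMNS,
    )


def power_from_adjusted_pvalues(padj: np.ndarray, alpha: float) -> np.ndarray:
    """Per-gene power from a genes x repetitions matrix of adjusted p-values.

    ``power_g`` is the fraction of the B columns with ``p_adj < alpha``;
    NaN entries (gene not evaluated in that repetition) count as
    non-significant while the denominator stays B, so power is always a
    multiple of 1/B in [0, 1].
    """
    padj = np.atleast_2d(np.asarray(padj, dtype=float))
    with np.errstate(invalid="ignore"):
        sig = np.where(np.isnan(padj), False, padj < alpha)
    return sig.sum(axis=1) / padj.shape[1]


def estimate_power(
    sel: ROISelection,
    ds: SpotDataset,
    spec: BootstrapSpec,
    de_options: DEOptions | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full bootstrap -> normalize -> DE -> power pipeline.

    Returns the power table (one row per gene ever evaluated) with columns
    ``gene, pi_g, abs_beta_g, N, power, B, alpha``.  ``pi_g`` is the mean of
    ``(pct1 + pct2) / 2`` and ``abs_beta_g`` the mean of ``|avg_logfc|``
    over the repetitions in which the gene passed the prefilter; genes that
    never passed it in any repetition are omitted.
    """
    opts = de_options or DEOptions()
    n_total = opts.n_genes_total if opts.n_genes_total is not None else ds.n_genes
    G, B = ds.n_genes, spec.B
    counts = sp.csc_matrix(ds.counts)

    padj = np.full((G, B), np.nan)
    pi_sum = np.zeros(G)
    beta_sum = np.zeros(G)
    n_eval = np.zeros(G, dtype=int)
    for b in range(B):
        idxA, idxB = bootstrap_replicates(sel, ds, spec, b)
        xa = lognormalize(counts[:, idxA])
        xb = lognormalize(counts[:, idxB])
        res = wilcoxon_de(
            xa,
            xb,
            n_genes_total=n_total,
            min_pct=opts.min_pct,
            logfc_threshold=opts.logfc_threshold,
            gene_ids=ds.gene_ids,
        )
        t = res["tested"].to_numpy()
        padj[:, b] = res["p_adj"].to_numpy()
        pi_sum[t] += (res["pct1"].to_numpy()[t] + res["pct2"].to_numpy()[t]) / 2.0
        beta_sum[t] += np.abs(res["avg_logfc"].to_numpy()[t])
        n_eval[t] += 1
        if progress:
            print(f"repetition {b + 1}/{B}", flush=True)

    power = power_from_adjusted_pvalues(padj, spec.alpha)
    keep = n_eval > 0
    return pd.DataFrame(
        {
            "gene": ds.gene_ids[keep],
            "pi_g": pi_sum[keep] / n_eval[keep],
            "abs_beta_g": beta_sum[keep] / n_eval[keep],
            "N": spec.N_label,
            "power": power[keep],
            "B": B,
            "alpha": spec.alpha,
        },
        columns=POWER_COLUMNS,
    )


def power_vs_null_check(records: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """QC summary of estimated power against a ground-truth DEG table.

    ``truth`` has columns ``gene, true_logfc``.  Genes absent from the power
    table (never evaluated) enter with power 0.  Returns one row per
    ``|true_logfc|`` stratum (stratum 0.0 = true nulls) with the stratum
    size and mean estimated power.
    """
    if truth is None or len(truth) == 0:
        raise ValidationError("ground-truth DEG table is empty")
    merged = truth.merge(records[["gene", "power"]], on="gene", how="left")
    merged["power"] = merged["power"].fillna(0.0)
    merged["stratum"] = np.abs(merged["true_logfc"].astype(float))
    out = (
        merged.groupby("stratum")
        .agg(n_genes=("gene", "size"), mean_power=("power", "mean"))
        .reset_index()
        .sort_values("stratum", ignore_index=True)
    )
    return out
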