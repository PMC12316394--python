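"""Synthetic two-condition Visium-like datasets with known ground truth.

Counts are negative-binomial in the mean/size parameterization
(``var = mu + mu^2/size``), the standard overdispersed model for RNA
counts.  A designated subset of genes is differentially expressed: in
condition 2 the mean of gene *g* is ``baseline_mean_g * 2**logfc_g``
(log2 fold changes, matching the effect-size axis used downstream).
Optional extra zeros thin the counts gene-wise (Bernoulli dropout), which
lowers the detection rate without touching the fold change of detected
spots, and an optional Gaussian-process field over the hex-grid spot
coordinates induces within-slice spatial autocorrelation of log-means.

The module also provides a direct Monte-Carlo "true power" oracle that
repeatedly draws fresh datasets from the generative model (no bootstrap)
and runs the same differential-expression test, giving an independent
standard against which the bootstrap power estimates can be judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataio import SpotDataset, ValidationError
from .power import DEOptions, wilcoxon_de

__all__ = ["SimulationDesign", "simulate_dataset", "truth_table", "true_power_oracle"]

#: Visium spots sit on a hexagonal grid with 100 units between spot centers.
HEX_SPACING = 100.0


@dataclass
class SimulationDesign:
    """Parameters of a two-condition spot-count simulation.

    ``baseline_mean``, ``dispersion`` and ``dropout_extra`` may be scalars
    (broadcast over genes) or per-gene vectors.  The first
    ``round(de_fraction * n_genes)`` genes are the differentially expressed
    set; ``logfc_values`` (scalar or one value per DEG) gives their log2
    fold changes and every other gene has log fold change exactly 0.
    ``spatial_corr_length`` is the squared-exponential kernel length scale
    in coordinate units (0 disables the field); ``spatial_sigma`` is the
    marginal standard deviation of the log-mean offsets.
    """

    n_genes: int
    n_slices_per_condition: int = 3
    spots_per_slice: int = 80
    baseline_mean: float | Sequence[float] = 2.0
    dispersion: float | Sequence[float] = 2.0
    de_fraction: float = 0.1
    logfc_values: float | Sequence[float] = 1.0
    dropout_extra: float | Sequence[float] = 0.0
    spatial_corr_length: float = 0.0
    spatial_sigma: float = 0.5
    seed: int = 0
    condition_labels: tuple[str, str] = ("cond1", "cond2")
    roi_label: str = "roi"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_slices_per_condition < 1 or self.spots_per_slice < 1:
            raise ValidationError("design needs >=1 gene, slice and spot per slice")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValidationError("de_fraction must be in [0, 1]")
        if self.spatial_corr_length < 0:
            raise ValidationError("spatial_corr_length must be >= 0")
        for name in ("baseline_mean", "dispersion"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v <= 0):
                raise ValidationError(f"{name} must be strictly positive")
        d = np.atleast_1d(np.asarray(self.dropout_extra, dtype=float))
        if np.any((d < 0) | (d >= 1)):
            raise ValidationError("dropout_extra must be in [0, 1)")

    # -- derived per-gene vectors -----------------------------------------
    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))

    def _per_gene(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(self.n_genes, float(arr))
        if arr.shape != (self.n_genes,):
            raise ValidationError(
                f"per-gene vector has shape {arr.shape}, expected ({self.n_genes},)"
            )
        return arr.copy()

    @property
    def means(self) -> np.ndarray:
        return self._per_gene(self.baseline_mean)

    @property
    def sizes(self) -> np.ndarray:
        return self._per_gene(self.dispersion)

    @property
    def dropouts(self) -> np.ndarray:
        return self._per_gene(self.dropout_extra)

    @property
    def logfc(self) -> np.ndarray:
        """Per-gene true log2 fold change (0 for non-DE genes)."""
        out = np.zeros(self.n_genes)
        k = self.n_de
        if k:
            vals = np.asarray(self.logfc_values, dtype=float)
            out[:k] = np.full(k, float(vals)) if vals.ndim == 0 else vals[:k]
        return out

    @property
    def gene_ids(self) -> np.ndarray:
        return np.array([f"gene{i:05d}" for i in range(self.n_genes)], dtype=object)


def hex_grid(n_spots: int, spacing: float = HEX_SPACING) -> np.ndarray:
    """Coordinates of ``n_spots`` points on a Visium-style hex grid."""
    side = max(1, math.ceil(math.sqrt(n_spots)))
    xy = np.empty((n_spots, 2))
    for i in range(n_spots):
        row, col = divmod(i, side)
        xy[i, 0] = spacing * (col + 0.5 * (row % 2))
        xy[i, 1] = spacing * row * math.sqrt(3) / 2
    return xy


def _gp_offsets(
    xy: np.ndarray, length: float, sigma: float, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean squared-exponential GP field per gene, (spots x genes)."""
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    cov = sigma**2 * np.exp(-d2 / (2.0 * length**2))
    cov[np.diag_indices_from(cov)] += 1e-8 * sigma**2
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((xy.shape[0], n_genes))


def simulate_dataset(design: SimulationDesign) -> SpotDataset:
    """Draw one two-condition dataset from the generative model.

    Fully reproducible from ``design.seed``: the same design always yields
    bit-identical counts.  The condition-2 mean of DE gene *g* is
    ``baseline * 2**logfc_g``; the GP offsets (if enabled) are centered so
    gene means are preserved on the natural scale.
    """
    rng = np.random.default_rng(design.seed)
    means = design.means
    sizes = design.sizes
    dropouts = design.dropouts
    fc = 2.0 ** design.logfc
    S = design.spots_per_slice
    xy_slice = hex_grid(S)

    blocks, barcodes, slice_ids, conditions, xys = [], [], [], [], []
    for ci, cond in enumerate(design.condition_labels):
        mu_cond = means * fc if ci == 1 else means
        for si in range(design.n_slices_per_condition):
            slice_id = f"{cond}_s{si}"
            mu = np.broadcast_to(mu_cond[:, None], (design.n_genes, S)).copy()
            if design.spatial_corr_length > 0:
                off = _gp_offsets(
                    xy_slice,
                    design.spatial_corr_length,
                    design.spatial_sigma,
                    design.n_genes,
                    rng,
                )  # spots x genes
                # exp(offset) has mean exp(sigma^2/2); recenter to keep means exact
                mu *= np.exp(off.T - 0.5 * design.spatial_sigma**2)
            p = sizes[:, None] / (sizes[:, None] + mu)
            counts = rng.negative_binomial(sizes[:, None], p, size=(design.n_genes, S))
            drop_mask = dropouts[:, None] > 0
            if drop_mask.any():
                keep = rng.random((design.n_genes, S)) >= dropouts[:, None]
                counts = np.where(keep, counts, 0)
            blocks.append(sp.csr_matrix(counts))
            barcodes.extend(f"{slice_id}:spot{j:04d}" for j in range(S))
            slice_ids.extend([slice_id] * S)
            conditions.extend([cond] * S)
            xys.append(xy_slice)

    return SpotDataset(
        counts=sp.hstack(blocks, format="csr"),
        gene_ids=design.gene_ids,
        spot_barcodes=np.array(barcodes, dtype=object),
        spot_xy=np.vstack(xys),
        slice_ids=np.array(slice_ids, dtype=object),
        roi_labels=np.full(len(slice_ids), design.roi_label, dtype=object),
        conditions=np.array(conditions, dtype=object),
    )


def truth_table(design: SimulationDesign) -> pd.DataFrame:
    """Ground-truth DEG table: one row per gene with its true log2 FC."""
    return pd.DataFrame({"gene": design.gene_ids, "true_logfc": design.logfc})


def true_power_oracle(
    design: SimulationDesign,
    gene: int,
    n_spots: int,
    N: int,
    alpha: float,
    n_genes_tested: int,
    reps: int,
    seed: int,
    de_options: DEOptions | None = None,
) -> float:
    """Monte-Carlo power of the DE test under the generative model itself.

    Each repetition draws a *fresh* experiment of ``N`` slices x ``n_spots``
    spots per condition from the design (all genes, so library sizes are
    realistic), normalizes, applies the same detection/fold-change prefilter
    as the bootstrap pipeline, and tests the target gene with a Bonferroni
    factor of ``n_genes_tested``.  Returns the rejection fraction in [0, 1].

    This is the independent standard for the bootstrap estimator: it uses
    the true population, not resampling.
    """
    if not 0 <= gene < design.n_genes:
        raise ValidationError(f"gene index {gene} out of range")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    opts = de_options or DEOptions()
    hits = 0
    for r in range(reps):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        rep_design = replace(
            design,
            n_slices_per_condition=N,
            spots_per_slice=n_spots,
            seed=rep_seed,
        )
        ds = simulate_dataset(rep_design)
        lib = np.asarray(ds.counts.sum(axis=0)).ravel()
        row = np.asarray(ds.counts[gene].todense()).ravel()
        xnorm = np.log1p(1e4 * row / lib)
        grpA = ds.conditions == design.condition_labels[0]
        res = wilcoxon_de(
            xnorm[grpA][None, :],
            xnorm[~grpA][None, :],
            n_genes_total=n_genes_tested,
            min_pct=opts.min_pct,
            logfc_threshold=opts.logfc_threshold,
            gene_ids=[str(ds.gene_ids[gene])],
        )
        rowres = res.iloc[0]
        if rowres["tested"] and rowres["p_adj"] < alpha:
            hits += 1
    return hits / reps
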