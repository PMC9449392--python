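"""Population-structure layer: distances, NJ tree, Patterson PCA, LD decay.

The pairwise distance is 1 - IBS (identity by state) from dosages; the
neighbour-joining construction is delegated to scikit-bio's Saitou-Nei
implementation and returned as a TreeNode with Newick support. PCA follows
the Patterson genotype normalisation (centre by 2*p-hat, scale by
sqrt(p-hat*(1-p-hat))); LD decay reproduces the PopLDdecay-style filtered
mean-r^2-by-distance-bin curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from sweepscan.core_io import MISSING, VariantMatrix


@dataclass
class DistanceResult:
    ids: list[str]
    matrix: np.ndarray


@dataclass
class PCAResult:
    eigenvalues: np.ndarray      # non-increasing
    coordinates: np.ndarray      # (n_samples, n_pcs): eigenvector * sqrt(eigenvalue)
    sample_ids: list[str]


@dataclass
class LDDecayCurve:
    bin_edges: np.ndarray        # bp, len nbins+1, covering (0, max_dist]
    mean_r2: np.ndarray          # NaN for empty bins
    pair_counts: np.ndarray


def pairwise_distance(vm: VariantMatrix) -> DistanceResult:
    """1 - IBS allele-sharing distance between all sample pairs.

    With dosages g_i, g_j the per-site shared fraction is (2 - |g_i - g_j|)/2,
    averaged over sites non-missing in both samples, so identical samples are
    at distance 0 and opposite homozygotes at 1.
    """
    if vm.n_samples < 2:
        raise ValueError("need at least two samples")
    g = vm.genotypes.astype(float)
    g[vm.genotypes == MISSING] = np.nan
    n = vm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[:, i:i + 1] - g[:, i + 1:])      # (snps, n-i-1)
        shared = np.sum(~np.isnan(diff), axis=0)
        if np.any(shared == 0):
            j = i + 1 + int(np.flatnonzero(shared == 0)[0])
            raise ValueError(
                f"samples {vm.sample_ids[i]!r} and {vm.sample_ids[j]!r} share "
                "no non-missing sites"
            )
        d_row = np.nansum(diff, axis=0) / (2.0 * shared)
        d[i, i + 1:] = d_row
        d[i + 1:, i] = d_row
    return DistanceResult(list(vm.sample_ids), d)


def neighbor_joining(dist: DistanceResult | np.ndarray, ids=None) -> TreeNode:
    """Saitou-Nei neighbour joining; exact on additive distance matrices.

    Negative branch lengths are clamped to zero. Returns an unrooted
    scikit-bio TreeNode (Newick via ``str(tree)`` or ``tree.write``).
    """
    if isinstance(dist, DistanceResult):
        ids, matrix = dist.ids, dist.matrix
    else:
        matrix = np.asarray(dist, float)
        if ids is None:
            ids = [f"t{i}" for i in range(matrix.shape[0])]
    if matrix.shape[0] < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(matrix < 0):
        raise ValueError("distance matrix has negative entries")
    dm = SkbioDistanceMatrix(matrix, ids=list(ids))
    return _skbio_nj(dm, neg_as_zero=True)


def pca_patterson(vm: VariantMatrix, n_components: int | None = None) -> PCAResult:
    """PCA with Patterson genotype normalisation.

    Each SNP row is centred by twice its sample allele frequency and scaled
    by sqrt(p_hat*(1-p_hat)); missing dosages are mean-imputed (zero after
    centring); zero-variance SNPs are dropped. Coordinates are unit
    eigenvectors of the sample-by-sample covariance scaled by the square
    root of their eigenvalues.
    """
    if vm.n_samples < 2:
        raise ValueError("need at least two samples")
    g = vm.genotypes.astype(float)
    g[vm.genotypes == MISSING] = np.nan
    n_ok = np.sum(~np.isnan(g), axis=1)
    keep = n_ok > 0
    g = g[keep]
    p_hat = np.nanmean(g, axis=1) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    g = g[poly]
    p_hat = p_hat[poly]
    x = (g - 2.0 * p_hat[:, None]) / np.sqrt(p_hat * (1.0 - p_hat))[:, None]
    x[np.isnan(x)] = 0.0
    n_snps = x.shape[0]
    if n_snps == 0:
        raise ValueError("no polymorphic SNPs for PCA")
    cov = (x.T @ x) / n_snps
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if n_components is not None:
        evals = evals[:n_components]
        evecs = evecs[:, :n_components]
    coords = evecs * np.sqrt(evals)[None, :]
    return PCAResult(evals, coords, list(vm.sample_ids))


def _snp_filter_mask(vm: VariantMatrix, sample_idx, maf_min, max_het, max_miss):
    g = vm.genotypes[:, sample_idx]
    ok = g != MISSING
    n = ok.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(ok, g, 0).sum(axis=1) / (2.0 * n)
        het = np.where(ok, g == 1, False).sum(axis=1) / n
        miss = 1.0 - n / g.shape[1]
    maf = np.minimum(p, 1.0 - p)
    return (n > 0) & (maf > maf_min) & (het <= max_het) & (miss <= max_miss)


def ld_r2(
    vm: VariantMatrix,
    sample_idx: np.ndarray | None = None,
    maf_min: float = 0.05,
    max_dist: int = 1_000_000,
    max_het: float = 0.9,
    max_miss: float = 0.1,
    bin_size: int = 1_000,
    use_haplotypes: bool | None = None,
) -> LDDecayCurve:
    """Mean r^2 between SNP pairs, binned by physical distance.

    SNPs are filtered first (MAF strictly > ``maf_min``; per-SNP heterozygote
    and missing fractions at most ``max_het`` / ``max_miss``); every retained
    pair within ``max_dist`` bp contributes. r^2 comes from phased haplotypes
    when available (D^2 / p_A(1-p_A)p_B(1-p_B), equivalently the squared
    Pearson correlation of the binary haplotype vectors), otherwise from the
    squared correlation of dosages.
    """
    if sample_idx is None:
        sample_idx = np.arange(vm.n_samples)
    keep = _snp_filter_mask(vm, sample_idx, maf_min, max_het, max_miss)
    pos = vm.positions[keep]
    if use_haplotypes is None:
        use_haplotypes = vm.haplotypes is not None
    if use_haplotypes:
        if vm.haplotypes is None:
            raise ValueError("no haplotypes available")
        hap_cols = np.sort(np.concatenate([2 * sample_idx, 2 * sample_idx + 1]))
        data = vm.haplotypes[np.ix_(np.flatnonzero(keep), hap_cols)].astype(float)
    else:
        data = vm.genotypes[np.ix_(np.flatnonzero(keep), sample_idx)].astype(float)
        data[data == MISSING] = np.nan

    n_bins = int(np.ceil(max_dist / bin_size))
    edges = np.arange(0, (n_bins + 1) * bin_size, bin_size)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    m = len(pos)
    if m >= 2:
        # centre rows ignoring NaN, then accumulate pair correlations in
        # blocks to bound memory
        mean = np.nanmean(data, axis=1)
        xc = data - mean[:, None]
        xc[np.isnan(xc)] = 0.0
        norm = np.sqrt(np.sum(xc**2, axis=1))
        block = 512
        for i0 in range(0, m, block):
            i1 = min(i0 + block, m)
            # partner range for each row: strictly later SNPs within max_dist
            j_hi = np.searchsorted(pos, pos[i0:i1] + max_dist, side="right")
            j_max = int(j_hi.max())
            sub = xc[i0:j_max]
            numer = xc[i0:i1] @ sub.T                      # (blk, j_max-i0)
            denom = norm[i0:i1, None] * norm[i0:j_max][None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = (numer / denom) ** 2
            for bi, i in enumerate(range(i0, i1)):
                js = np.arange(i + 1, j_hi[bi])
                if len(js) == 0:
                    continue
                dvec = pos[js] - pos[i]
                vals = r2[bi, js - i0]
                ok = np.isfinite(vals) & (dvec > 0) & (dvec <= max_dist)
                if not np.any(ok):
                    continue
                b = np.minimum((dvec[ok] - 1) // bin_size, n_bins - 1).astype(int)
                np.add.at(sums, b, vals[ok])
                np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges, mean_r2, counts)


def write_phylip_distance(dist: DistanceResult, path) -> None:
    """PHYLIP square distance-matrix format (for external NJ cross-checks)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist.ids):5d}\n")
        for i, name in enumerate(dist.ids):
            row = " ".join(f"{x:.6f}" for x in dist.matrix[i])
            fh.write(f"{name[:10]:<10s} {row}\n")
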