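"""Frequency-based selection statistics over sliding windows.

Implements the four-track scan logic used for sweep detection in an admixed
breed and its parents:

* pooled heterozygosity  Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ)+sum(nMIN))**2
  over the SNPs of a window (Rubin-style, from genotype-derived allele counts);
* per-SNP Weir & Cockerham (1984) two-population FST from the a, b, c
  variance components, averaged arithmetically per window;
* nucleotide diversity theta-pi per bp and its log2 ratio between two
  populations;
* genome-wide Z-transformation (population sd) and strict-inequality
  thresholding, with multi-evidence combination of candidate windows.

Missing values (windows below ``min_snps``, undefined estimators, zero
denominators) are NaN throughout and are excluded from Z-transformation and
never selected as candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sweepscan.core_io import MISSING, VariantMatrix
from sweepscan.windows import Window

DEFAULT_MIN_SNPS = 10


# ---------------------------------------------------------------------------
# allele counts

def allele_counts(vm: VariantMatrix, sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (ref_count, alt_count) of non-missing alleles in a sample set."""
    g = vm.genotypes[:, sample_idx].astype(np.int64)
    ok = g != MISSING
    alt = np.where(ok, g, 0).sum(axis=1)
    total = 2 * ok.sum(axis=1)
    return total - alt, alt


def major_minor_counts(vm: VariantMatrix, sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref, alt = allele_counts(vm, sample_idx)
    return np.maximum(ref, alt), np.minimum(ref, alt)


# ---------------------------------------------------------------------------
# pooled heterozygosity

def pooled_heterozygosity(n_major: np.ndarray, n_minor: np.ndarray) -> float:
    """Hp of one window from per-SNP major/minor allele counts.

    Symmetric in the major/minor labelling because only the two sums enter;
    bounded in [0, 0.5]. Returns NaN for an empty window (all counts zero).
    """
    smaj = float(np.sum(n_major))
    smin = float(np.sum(n_minor))
    tot = smaj + smin
    if tot == 0:
        return float("nan")
    return 2.0 * smaj * smin / (tot * tot)


def hp_track(
    vm: VariantMatrix,
    wins: list[Window],
    sample_idx: np.ndarray,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> np.ndarray:
    """Per-window Hp for one population; NaN below min_snps informative SNPs."""
    nmaj, nmin = major_minor_counts(vm, sample_idx)
    out = np.full(len(wins), np.nan)
    for i, w in enumerate(wins):
        idx = w.snp_indices
        if idx is None:
            raise ValueError("windows lack snp_indices; run assign_snps first")
        informative = idx[(nmaj[idx] + nmin[idx]) > 0]
        if len(informative) < min_snps:
            continue
        out[i] = pooled_heterozygosity(nmaj[informative], nmin[informative])
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham FST

def _wc_components(
    ref_a: np.ndarray, alt_a: np.ndarray, ref_b: np.ndarray, alt_b: np.ndarray,
    het_a: np.ndarray, het_b: np.ndarray, n_a: np.ndarray, n_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised W&C (1984) a, b, c variance components, r=2 populations.

    n_a, n_b are non-missing diploid sample sizes; het_* observed
    heterozygote counts. Sites where either population has no data yield NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = alt_a / (ref_a + alt_a)
        p_b = alt_b / (ref_b + alt_b)
        h_a = het_a / n_a
        h_b = het_b / n_b
        r = 2.0
        nbar = (n_a + n_b) / r
        nc = (r * nbar - (n_a**2 + n_b**2) / (r * nbar)) / (r - 1.0)
        pbar = (n_a * p_a + n_b * p_b) / (r * nbar)
        s2 = (n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n_a * h_a + n_b * h_b) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def snp_fst(
    vm: VariantMatrix,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    estimator: str = "wc",
) -> np.ndarray:
    """Per-SNP two-population FST.

    ``wc`` is the Weir & Cockerham (1984) variance-components estimator
    theta-hat = a/(a+b+c); ``hudson`` is the Hudson/Bhatia ratio estimator.
    Sites monomorphic in both populations, or with fewer than two non-missing
    alleles in either, are NaN.
    """
    g_a = vm.genotypes[:, idx_a].astype(np.int64)
    g_b = vm.genotypes[:, idx_b].astype(np.int64)
    ok_a = g_a != MISSING
    ok_b = g_b != MISSING
    n_a = ok_a.sum(axis=1).astype(float)
    n_b = ok_b.sum(axis=1).astype(float)
    alt_a = np.where(ok_a, g_a, 0).sum(axis=1).astype(float)
    alt_b = np.where(ok_b, g_b, 0).sum(axis=1).astype(float)
    ref_a = 2 * n_a - alt_a
    ref_b = 2 * n_b - alt_b

    bad = (n_a < 1) | (n_b < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = alt_a / (2 * n_a)
        p_b = alt_b / (2 * n_b)
    mono = ((alt_a + alt_b) == 0) | ((ref_a + ref_b) == 0)

    if estimator == "wc":
        het_a = np.where(ok_a, g_a == 1, False).sum(axis=1).astype(float)
        het_b = np.where(ok_b, g_b == 1, False).sum(axis=1).astype(float)
        a, b, c = _wc_components(ref_a, alt_a, ref_b, alt_b, het_a, het_b, n_a, n_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = a / (a + b + c)
    elif estimator == "hudson":
        with np.errstate(divide="ignore", invalid="ignore"):
            num = (p_a - p_b) ** 2 - p_a * (1 - p_a) / (2 * n_a - 1) - p_b * (1 - p_b) / (2 * n_b - 1)
            den = p_a * (1 - p_b) + p_b * (1 - p_a)
            fst = num / den
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    fst = np.asarray(fst, dtype=float)
    fst[bad | mono] = np.nan
    # <2 alleles in either population: estimator undefined
    fst[(2 * n_a < 2) | (2 * n_b < 2)] = np.nan
    return fst


def window_mean(per_snp: np.ndarray, wins: list[Window], min_snps: int = DEFAULT_MIN_SNPS) -> np.ndarray:
    """Arithmetic mean of defined per-SNP values per window (NaN below min_snps)."""
    out = np.full(len(wins), np.nan)
    for i, w in enumerate(wins):
        vals = per_snp[w.snp_indices]
        vals = vals[~np.isnan(vals)]
        if len(vals) >= min_snps:
            out[i] = float(np.mean(vals))
    return out


def window_fst(
    vm: VariantMatrix,
    wins: list[Window],
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    min_snps: int = DEFAULT_MIN_SNPS,
    estimator: str = "wc",
    ratio_of_sums: bool = False,
) -> np.ndarray:
    """Window-averaged FST: mean of per-SNP estimates (default) or
    ratio-of-sums of the W&C components for robustness comparisons."""
    if not ratio_of_sums:
        return window_mean(snp_fst(vm, idx_a, idx_b, estimator), wins, min_snps)
    if estimator != "wc":
        raise ValueError("ratio_of_sums requires the wc estimator")
    g_a = vm.genotypes[:, idx_a].astype(np.int64)
    g_b = vm.genotypes[:, idx_b].astype(np.int64)
    ok_a, ok_b = g_a != MISSING, g_b != MISSING
    n_a = ok_a.sum(axis=1).astype(float)
    n_b = ok_b.sum(axis=1).astype(float)
    alt_a = np.where(ok_a, g_a, 0).sum(axis=1).astype(float)
    alt_b = np.where(ok_b, g_b, 0).sum(axis=1).astype(float)
    het_a = np.where(ok_a, g_a == 1, False).sum(axis=1).astype(float)
    het_b = np.where(ok_b, g_b == 1, False).sum(axis=1).astype(float)
    a, b, c = _wc_components(2 * n_a - alt_a, alt_a, 2 * n_b - alt_b, alt_b,
                             het_a, het_b, n_a, n_b)
    defined = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    out = np.full(len(wins), np.nan)
    for i, w in enumerate(wins):
        idx = w.snp_indices[defined[w.snp_indices]]
        if len(idx) < min_snps:
            continue
        denom = np.sum(a[idx] + b[idx] + c[idx])
        out[i] = np.sum(a[idx]) / denom if denom != 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# nucleotide diversity

def theta_pi_track(
    vm: VariantMatrix,
    wins: list[Window],
    sample_idx: np.ndarray,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> np.ndarray:
    """Per-bp nucleotide diversity per window for one population.

    theta_pi = sum over sites of 2*p*(1-p)*n/(n-1), divided by the window
    length in bp; n is the site's non-missing allele count. Windows with
    fewer than ``min_snps`` sites having n >= 2 are NaN (a window whose
    sites are all monomorphic in the population still counts them).
    """
    ref, alt = allele_counts(vm, sample_idx)
    n = (ref + alt).astype(float)
    out = np.full(len(wins), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n
        per_site = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    for i, w in enumerate(wins):
        idx = w.snp_indices
        usable = idx[n[idx] >= 2]
        if len(usable) < min_snps:
            continue
        out[i] = float(np.sum(per_site[usable])) / (w.end - w.start)
    return out


def pi_ratio_log2(
    track_num: np.ndarray, track_den: np.ndarray, pseudocount: float = 0.0
) -> np.ndarray:
    """log2 of the per-window theta-pi ratio.

    Windows with a zero denominator or a missing value in either track are
    NaN (never +-inf); an optional pseudocount added to both is available for
    very small simulated windows.
    """
    track_num = np.asarray(track_num, float)
    track_den = np.asarray(track_den, float)
    if track_num.shape != track_den.shape:
        raise ValueError("theta-pi tracks cover different window universes")
    num = track_num + pseudocount
    den = track_den + pseudocount
    out = np.full(track_num.shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0) & (num > 0)
    out[ok] = np.log2(num[ok] / den[ok])
    return out


# ---------------------------------------------------------------------------
# Z-transformation, thresholds, evidence combination

def z_transform(values: np.ndarray, name: str = "track") -> np.ndarray:
    """Genome-wide Z-score with population (divide-by-N) sd; NaN propagates."""
    values = np.asarray(values, float)
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError(f"{name}: need >= 2 non-missing windows to Z-transform")
    mu = values[ok].mean()
    sd = values[ok].std(ddof=0)
    if sd == 0:
        raise ValueError(f"{name}: zero spread, Z-transform undefined")
    out = np.full(values.shape, np.nan)
    out[ok] = (values[ok] - mu) / sd
    return out


@dataclass
class ScanTrack:
    """One statistic over the window universe, with its threshold rule."""

    name: str
    windows: list[Window]
    raw: np.ndarray
    z: np.ndarray | None = None
    threshold: float = 0.0
    direction: str = "greater"       # "greater" | "less"
    on_z: bool = False               # threshold applies to z rather than raw
    comparison: str = ""             # e.g. "HYB vs PARENT_A"

    def values(self) -> np.ndarray:
        return self.z if self.on_z else self.raw

    def pass_mask(self) -> np.ndarray:
        v = self.values()
        with np.errstate(invalid="ignore"):
            if self.direction == "less":
                m = v < self.threshold
            elif self.direction == "greater":
                m = v > self.threshold
            else:
                raise ValueError(f"unknown direction {self.direction!r}")
        m[~np.isfinite(v)] = False
        return m


@dataclass
class CandidateSet:
    """Windows passing a threshold, keyed by (contig, start) with provenance."""

    keys: set[tuple[str, int]]
    provenance: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    name: str = ""

    def __len__(self) -> int:
        return len(self.keys)


def select_candidates(track: ScanTrack) -> CandidateSet:
    """Windows strictly beyond the track's threshold; missing never selected."""
    mask = track.pass_mask()
    keys = {track.windows[i].key for i in np.flatnonzero(mask)}
    return CandidateSet(keys=keys, provenance={k: [track.name] for k in keys},
                        name=track.name)


def percentile_threshold(track: ScanTrack, pct: float) -> ScanTrack:
    """Return the track with its threshold replaced by the empirical
    percentile of its (z or raw) values — used at small genome sizes where
    the fixed literature cut-offs are unreachable."""
    v = track.values()
    v = v[np.isfinite(v)]
    track.threshold = float(np.percentile(v, pct))
    return track


def combine_evidence(sets: list[CandidateSet], min_methods: int = 2) -> CandidateSet:
    """Windows present in at least ``min_methods`` candidate sets.

    min_methods=1 is the union; min_methods=len(sets) the intersection.
    Provenance lists the supporting method names per window.
    """
    if min_methods < 1:
        raise ValueError("min_methods must be >= 1")
    support: dict[tuple[str, int], list[str]] = {}
    for cs in sets:
        for k in cs.keys:
            support.setdefault(k, []).extend(cs.provenance.get(k, [cs.name]))
    keys = {k for k, methods in support.items() if len(set(methods)) >= min_methods}
    return CandidateSet(
        keys=keys,
        provenance={k: sorted(set(support[k])) for k in keys},
        name=f">={min_methods} methods",
    )
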