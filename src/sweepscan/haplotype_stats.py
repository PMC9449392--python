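"""Haplotype-based selection statistics: EHH, iHH and XP-EHH.

EHH at distance x from a core SNP is the probability that two haplotypes
drawn without replacement are identical over the stretch from the core out
to x: EHH(x) = sum_h C(c_h, 2) / C(n, 2) over the counts c_h of distinct
extended haplotypes. It is computed over ALL haplotypes of a population
(so EHH(0) is the core-site homozygosity), which keeps the cross-population
ratio defined even when a core is monomorphic in one population; per-allele
curves are available for diagnostics.

iHH integrates EHH against physical distance (trapezoid) in both directions;
XP-EHH is ln(iHH_A / iHH_B), reported unstandardized so the 0.7 window-mean
cut-off semantics can be applied literally, with optional genome-wide
normalisation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np

from sweepscan.windows import Window
from sweepscan.sweep_stats import window_mean, DEFAULT_MIN_SNPS

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000


@dataclass
class EHHCurve:
    core: int                 # SNP index of the core
    direction: str            # "upstream" (towards 0) or "downstream"
    distances: np.ndarray     # bp from core, starting at 0
    ehh: np.ndarray           # homozygosity at each breakpoint, ehh[0] at the core


def _homozygosity(groups: np.ndarray) -> float:
    """sum_h C(c_h,2) / C(n,2) for a vector of group labels."""
    n = len(groups)
    if n < 2:
        return 0.0
    _, counts = np.unique(groups, return_counts=True)
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def ehh(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: str,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
    core_allele: int | None = None,
) -> EHHCurve:
    """EHH decay curve from a core SNP in one direction.

    ``haps`` is (n_haplotypes, n_snps) binary; ``positions`` bp, sorted.
    Extension stops once EHH drops below ``cutoff`` or an inter-SNP gap
    exceeds ``max_gap`` bp. With ``core_allele`` set, only carriers of that
    allele at the core are considered (classic per-allele EHH, which starts
    at 1).
    """
    haps = np.asarray(haps)
    if haps.ndim != 2:
        raise ValueError("haps must be a 2-D haplotype matrix")
    if np.any(haps < 0):
        raise ValueError("haplotype matrix contains missing/unphased entries")
    n_hap, n_snp = haps.shape
    if not 0 <= core < n_snp:
        raise ValueError(f"core index {core} out of range")
    if n_hap < 2:
        raise ValueError("need at least two haplotypes")
    if direction not in ("upstream", "downstream"):
        raise ValueError(f"unknown direction {direction!r}")

    if core_allele is None:
        rows = np.arange(n_hap)
    else:
        rows = np.flatnonzero(haps[:, core] == core_allele)
        if len(rows) < 2:
            raise ValueError("fewer than two carriers of the core allele")

    # Columns from the core outward; the core column itself defines the
    # grouping at distance 0 (all-haplotype mode). In per-allele mode every
    # considered haplotype shares the core allele, so the first column is
    # constant and EHH(0) = 1.
    if direction == "upstream":
        cols = np.arange(core, -1, -1)
    else:
        cols = np.arange(core, n_snp)
    seq = np.ascontiguousarray(haps[np.ix_(rows, cols)].astype(np.uint8))
    if core_allele is not None:
        seq[:, 0] = 0
    m, length = seq.shape

    # Sort haplotypes lexicographically along the extension (memcmp on the
    # raw bytes equals column-wise lexicographic order for 0/1 values), then
    # record for each adjacent sorted pair the first column where they
    # differ: at extension step k the groups are the runs between pairs with
    # first-difference <= k. Sorting once replaces per-step regrouping.
    order = np.argsort(seq.view(np.dtype((np.void, length))).ravel())
    s = seq[order]
    neq = s[1:] != s[:-1]
    has_diff = neq.any(axis=1)
    first_diff = np.where(has_diff, neq.argmax(axis=1), length)

    # EHH is piecewise constant in k with at most m-1 change points (one per
    # boundary), so process boundary-appearance events in order of their
    # first-difference column and accumulate the shared-pair count.
    denom = float(m * (m - 1))
    bound_rows = np.flatnonzero(first_diff < length)
    ev_order = np.argsort(first_diff[bound_rows], kind="stable")
    cut: list[int] = []          # active boundaries (sorted row indices)
    pairs = m * (m - 1)
    ev_k: list[int] = []
    ev_pairs: list[int] = []
    for b in bound_rows[ev_order]:
        i = bisect.bisect_left(cut, int(b))
        lo = (cut[i - 1] + 1) if i > 0 else 0
        hi = (cut[i] + 1) if i < len(cut) else m
        n0, n1, n2 = hi - lo, b + 1 - lo, hi - b - 1
        pairs += -n0 * (n0 - 1) + n1 * (n1 - 1) + n2 * (n2 - 1)
        cut.insert(i, int(b))
        ev_k.append(int(first_diff[b]))
        ev_pairs.append(pairs)
    ev_k_arr = np.array(ev_k, dtype=np.int64)
    ev_pairs_arr = np.array(ev_pairs, dtype=np.int64)

    ks = np.arange(length)
    if ev_k_arr.size:
        idx = np.searchsorted(ev_k_arr, ks, side="right") - 1
        ehh_vec = np.where(idx >= 0, ev_pairs_arr[np.maximum(idx, 0)], m * (m - 1)) / denom
    else:
        ehh_vec = np.ones(length)

    # truncation: inter-SNP gap exceeding max_gap, then first dip below cutoff
    last = length - 1
    if length > 1:
        gaps = np.abs(np.diff(positions[cols].astype(np.int64)))
        viol = np.flatnonzero(gaps > max_gap)
        if viol.size:
            last = min(last, int(viol[0]))  # stop before the offending step
    below = np.flatnonzero(ehh_vec[: last + 1] < cutoff)
    if below.size:
        last = int(below[0])
    dists = np.abs(positions[cols[: last + 1]].astype(np.int64) - int(positions[core])).astype(float)
    return EHHCurve(core, direction, dists, ehh_vec[: last + 1])


def ihh(up: EHHCurve, down: EHHCurve) -> float:
    """Integrated EHH: trapezoid over physical distance, both sides summed.

    A side with no flanking SNP (single-point curve) contributes 0.
    """
    total = 0.0
    for c in (up, down):
        if len(c.distances) >= 2:
            total += float(np.trapezoid(c.ehh, c.distances))
    return total


def site_ihh(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
) -> float:
    up = ehh(haps, positions, core, "upstream", cutoff, max_gap)
    down = ehh(haps, positions, core, "downstream", cutoff, max_gap)
    return ihh(up, down)


def xpehh(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    positions: np.ndarray,
    core: int,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
) -> float:
    """Unstandardized ln(iHH_A / iHH_B) at one core SNP.

    Exactly antisymmetric under swapping the populations. NaN when either
    population's iHH is zero. Positive values mean longer haplotypes in the
    first-named population.
    """
    ihh_a = site_ihh(haps_a, positions, core, cutoff, max_gap)
    ihh_b = site_ihh(haps_b, positions, core, cutoff, max_gap)
    if ihh_a <= 0.0 or ihh_b <= 0.0:
        return float("nan")
    return float(np.log(ihh_a) - np.log(ihh_b))


def xpehh_scan(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    positions: np.ndarray,
    cores: np.ndarray | None = None,
    cutoff: float = EHH_CUTOFF,
    max_gap: int = MAX_GAP_BP,
) -> np.ndarray:
    """Per-core-SNP XP-EHH over the shared SNP set (all SNPs by default).

    Returns an array aligned with ``positions`` (NaN at unevaluated or
    undefined cores).
    """
    n_snp = len(positions)
    out = np.full(n_snp, np.nan)
    if cores is None:
        cores = np.arange(n_snp)
    for c in cores:
        out[c] = xpehh(haps_a, haps_b, positions, int(c), cutoff, max_gap)
    return out


def window_xpehh(
    per_snp: np.ndarray,
    wins: list[Window],
    min_snps: int = DEFAULT_MIN_SNPS,
) -> np.ndarray:
    """Arithmetic mean of defined per-SNP XP-EHH values per window."""
    return window_mean(per_snp, wins, min_snps)


def normalize_xpehh(per_snp: np.ndarray) -> np.ndarray:
    """Optional genome-wide (mean 0, sd 1) normalisation of per-SNP XP-EHH."""
    ok = np.isfinite(per_snp)
    mu = per_snp[ok].mean()
    sd = per_snp[ok].std(ddof=0)
    out = np.full(per_snp.shape, np.nan)
    out[ok] = (per_snp[ok] - mu) / sd
    return out
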