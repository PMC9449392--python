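"""Whole-scan orchestration: the four-statistic window scan in one call.

Given filtered variant matrices, a population map and a scan configuration,
computes per-window pooled heterozygosity (Z-transformed), window-averaged
Weir-Cockerham FST (Z-transformed), window-mean XP-EHH and the log2
theta-pi ratio for a focal population against one or more references,
extracts candidate windows per statistic family and combines evidence
across families.

Thresholds run in two modes: ``fixed`` applies the literature cut-offs
(Z(Hp) < -4, Z(FST) > 4, XP-EHH > 0.7, log2 pi-ratio > 2); ``percentile``
replaces each comparison's cut-off with the empirical tail percentile of
its own track, which is the appropriate choice at simulated genome sizes
where +-4 sd outliers cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sweepscan.core_io import PopulationMap, VariantMatrix
from sweepscan.haplotype_stats import (
    EHH_CUTOFF,
    MAX_GAP_BP,
    window_xpehh,
    xpehh_scan,
)
from sweepscan.sweep_stats import (
    CandidateSet,
    ScanTrack,
    combine_evidence,
    hp_track,
    pi_ratio_log2,
    select_candidates,
    theta_pi_track,
    window_fst,
    z_transform,
)
from sweepscan.windows import Window, assign_snps, make_windows


@dataclass
class ScanConfig:
    focal: str = "H"                      # population scanned for sweeps
    references: tuple[str, ...] = ("A", "B")
    window_size: int = 100_000
    step: int = 50_000
    min_snps: int = 10
    zhp_threshold: float = -4.0
    zfst_threshold: float = 4.0
    xpehh_threshold: float = 0.7
    piratio_threshold: float = 2.0
    threshold_mode: str = "fixed"         # "fixed" | "percentile"
    tail_percent: float = 1.0             # tail mass per track in percentile mode
    min_methods: int = 2
    fst_estimator: str = "wc"
    # pi-ratio direction: "reference" numerator flags LOW focal diversity at
    # the high tail (sweep-in-focal logic); "focal" reproduces the published
    # labelling literally.
    pi_numerator: str = "reference"
    ehh_cutoff: float = EHH_CUTOFF
    max_gap: int = MAX_GAP_BP
    flank: int = 50_000


@dataclass
class ScanResult:
    windows: list[Window]
    tracks: dict[str, ScanTrack]
    family_candidates: dict[str, CandidateSet]
    combined: CandidateSet
    per_track_candidates: dict[str, CandidateSet] = field(default_factory=dict)


def _hap_matrix(vm: VariantMatrix, sample_idx: np.ndarray) -> np.ndarray:
    if vm.haplotypes is None:
        raise ValueError("XP-EHH requires phased haplotypes")
    cols = np.empty(2 * len(sample_idx), dtype=np.intp)
    cols[0::2] = 2 * sample_idx
    cols[1::2] = 2 * sample_idx + 1
    return vm.haplotypes[:, cols].T  # (n_hap, n_snps)


def run_scan(
    vms: dict[str, VariantMatrix],
    pmap: PopulationMap,
    contig_lengths: dict[str, int],
    cfg: ScanConfig,
) -> ScanResult:
    """Run the full four-statistic scan over every contig."""
    for pop in (cfg.focal, *cfg.references):
        if pop not in pmap.populations:
            raise ValueError(f"population {pop!r} missing from the population map")

    contigs = sorted(vms)
    all_windows: list[Window] = []
    per_contig_windows: dict[str, list[Window]] = {}
    for contig in contigs:
        wins = make_windows(contig, contig_lengths[contig], cfg.window_size, cfg.step)
        assign_snps(wins, vms[contig])
        per_contig_windows[contig] = wins
        all_windows.extend(wins)

    def concat(fn) -> np.ndarray:
        return np.concatenate([fn(vms[c], per_contig_windows[c]) for c in contigs])

    first_vm = vms[contigs[0]]
    idx_focal = first_vm.sample_indices(pmap.samples(cfg.focal))
    ref_idx = {r: first_vm.sample_indices(pmap.samples(r)) for r in cfg.references}

    tracks: dict[str, ScanTrack] = {}

    hp_raw = concat(lambda vm, w: hp_track(vm, w, idx_focal, cfg.min_snps))
    tracks["ZHp"] = ScanTrack(
        name="ZHp", windows=all_windows, raw=hp_raw, z=z_transform(hp_raw, "ZHp"),
        threshold=cfg.zhp_threshold, direction="less", on_z=True,
        comparison=cfg.focal,
    )

    pi_focal = concat(lambda vm, w: theta_pi_track(vm, w, idx_focal, cfg.min_snps))
    for ref in cfg.references:
        fst_raw = concat(
            lambda vm, w: window_fst(vm, w, idx_focal, ref_idx[ref],
                                     cfg.min_snps, cfg.fst_estimator)
        )
        tracks[f"ZFst|{ref}"] = ScanTrack(
            name="ZFst", windows=all_windows, raw=fst_raw,
            z=z_transform(fst_raw, f"ZFst|{ref}"),
            threshold=cfg.zfst_threshold, direction="greater", on_z=True,
            comparison=f"{cfg.focal} vs {ref}",
        )

        xp_raw = concat(
            lambda vm, w: window_xpehh(
                xpehh_scan(
                    _hap_matrix(vm, idx_focal),
                    _hap_matrix(vm, ref_idx[ref]),
                    vm.positions,
                    cutoff=cfg.ehh_cutoff,
                    max_gap=cfg.max_gap,
                ),
                w, cfg.min_snps,
            )
        )
        tracks[f"XPEHH|{ref}"] = ScanTrack(
            name="XPEHH", windows=all_windows, raw=xp_raw,
            threshold=cfg.xpehh_threshold, direction="greater", on_z=False,
            comparison=f"{cfg.focal} (numerator) vs {ref}",
        )

        pi_ref = concat(lambda vm, w: theta_pi_track(vm, w, ref_idx[ref], cfg.min_snps))
        if cfg.pi_numerator == "reference":
            ratio = pi_ratio_log2(pi_ref, pi_focal)
            label = f"{ref}/{cfg.focal}"
        else:
            ratio = pi_ratio_log2(pi_focal, pi_ref)
            label = f"{cfg.focal}/{ref}"
        tracks[f"log2PiRatio|{ref}"] = ScanTrack(
            name="log2PiRatio", windows=all_windows, raw=ratio,
            threshold=cfg.piratio_threshold, direction="greater", on_z=False,
            comparison=label,
        )

    per_track_candidates: dict[str, CandidateSet] = {}
    family_sets: dict[str, CandidateSet] = {}
    for key, track in tracks.items():
        if cfg.threshold_mode == "percentile":
            v = track.values()
            v = v[np.isfinite(v)]
            pct = cfg.tail_percent if track.direction == "less" else 100.0 - cfg.tail_percent
            track.threshold = float(np.percentile(v, pct))
        elif cfg.threshold_mode != "fixed":
            raise ValueError(f"unknown threshold_mode {cfg.threshold_mode!r}")
        cand = select_candidates(track)
        per_track_candidates[key] = cand
        fam = family_sets.get(track.name)
        if fam is None:
            family_sets[track.name] = CandidateSet(
                keys=set(cand.keys),
                provenance={k: [track.name] for k in cand.keys},
                name=track.name,
            )
        else:
            fam.keys |= cand.keys
            for k in cand.keys:
                fam.provenance.setdefault(k, [track.name])

    combined = combine_evidence(list(family_sets.values()), cfg.min_methods)
    return ScanResult(
        windows=all_windows,
        tracks=tracks,
        family_candidates=family_sets,
        combined=combined,
        per_track_candidates=per_track_candidates,
    )


def track_table(result: ScanResult) -> "list[tuple]":
    """Rows (track_key, contig, start, end, n_snps, raw, z, passed) for TSV export."""
    rows = []
    for key, tr in result.tracks.items():
        mask = tr.pass_mask()
        for i, w in enumerate(tr.windows):
            z = "" if tr.z is None or not np.isfinite(tr.z[i]) else f"{tr.z[i]:.6g}"
            raw = "" if not np.isfinite(tr.raw[i]) else f"{tr.raw[i]:.6g}"
            rows.append((key, w.contig, w.start, w.end, w.n_snps, raw, z, int(mask[i])))
    return rows
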