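"""Candidate-window -> gene mapping with flanked selection regions.

Each candidate window is extended by a symmetric flank (default 50 kb,
clipped at zero) and intersected with the gene annotation; any >= 1 bp
overlap of the half-open intervals reports the gene, once, with the
provenance of every supporting window merged. Gene-level Venn-style counts
across statistics mirror the multi-method evidence combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from intervaltree import IntervalTree

from sweepscan.core_io import GeneSet
from sweepscan.sweep_stats import CandidateSet

DEFAULT_FLANK_BP = 50_000


@dataclass
class GeneHit:
    gene_id: str
    contig: str
    start: int
    end: int
    windows: list[tuple[str, int]] = field(default_factory=list)
    methods: list[str] = field(default_factory=list)


@dataclass
class CandidateGeneReport:
    flank: int
    hits: dict[str, GeneHit] = field(default_factory=dict)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def genes_in_windows(
    cands: CandidateSet,
    genes: GeneSet,
    window_size: int,
    contig_lengths: dict[str, int] | None = None,
    flank: int = DEFAULT_FLANK_BP,
    warn=None,
) -> CandidateGeneReport:
    """Genes overlapping any flank-extended candidate window.

    ``window_size`` reconstructs each window's end from its (contig, start)
    key, truncated at the contig length when known. Genes on contigs absent
    from the candidate namespace are skipped (``warn`` callback, if given,
    receives a message). Strand is ignored: the flank rule is symmetric.
    """
    trees: dict[str, IntervalTree] = {}
    for i in range(len(genes)):
        if genes.ends[i] > genes.starts[i]:
            trees.setdefault(genes.contigs[i], IntervalTree()).addi(
                int(genes.starts[i]), int(genes.ends[i]), i
            )
    known_contigs = {c for c, _ in cands.keys}
    for contig in set(genes.contigs) - known_contigs:
        if warn is not None and known_contigs:
            warn(f"gene contig {contig!r} absent from candidate windows; skipped")

    report = CandidateGeneReport(flank=flank)
    for key in sorted(cands.keys):
        contig, start = key
        end = start + window_size
        if contig_lengths and contig in contig_lengths:
            end = min(end, contig_lengths[contig])
        lo = max(0, start - flank)
        hi = end + flank
        tree = trees.get(contig)
        if tree is None:
            continue
        for iv in tree.overlap(lo, hi):
            gi = iv.data
            gid = genes.gene_ids[gi]
            hit = report.hits.get(gid)
            if hit is None:
                hit = GeneHit(gid, contig, int(genes.starts[gi]), int(genes.ends[gi]))
                report.hits[gid] = hit
            hit.windows.append(key)
            for m in cands.provenance.get(key, []):
                if m not in hit.methods:
                    hit.methods.append(m)
    return report


def per_method_gene_counts(reports: dict[str, CandidateGeneReport]) -> dict:
    """Venn-style table: per-track gene counts plus all intersections.

    Returns ``{"per_track": {name: count}, "pairwise": {(a, b): count},
    "all_tracks": count, "gene_sets": {name: set}}``.
    """
    sets = {name: rep.gene_ids for name, rep in reports.items()}
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(sorted(sets), 2)
    }
    all_tracks = set.intersection(*sets.values()) if sets else set()
    return {
        "per_track": {name: len(s) for name, s in sets.items()},
        "pairwise": pairwise,
        "all_tracks": len(all_tracks),
        "gene_sets": sets,
    }


def genes_detected_by_at_least(
    reports: dict[str, CandidateGeneReport], min_methods: int = 2
) -> set[str]:
    """Gene-level evidence combination (the alternative order to combining
    windows first): genes present in >= min_methods per-track reports."""
    counts: dict[str, int] = {}
    for rep in reports.values():
        for gid in rep.gene_ids:
            counts[gid] = counts.get(gid, 0) + 1
    return {g for g, c in counts.items() if c >= min_methods}
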