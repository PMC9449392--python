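"""Standard-format I/O and variant-level filtering.

Reads VCF 4.x into per-contig :class:`VariantMatrix` objects, applies the
quality / call-rate / adjacency filters that precede every scan statistic,
and handles the small text sidecar formats: two-column population maps,
BED/GFF3 gene annotations, FAI-style contig lengths and BED output.

Coordinate conventions: VCF and GFF3 are 1-based inclusive on disk;
everything in memory is 0-based half-open except ``VariantMatrix.positions``,
which keeps the 1-based VCF POS so that reports match the input file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING = -1  # genotype dosage code for missing


@dataclass
class VariantMatrix:
    """Biallelic-SNP-oriented genotype container for one contig.

    genotypes holds alternate-allele dosage {0,1,2} with MISSING=-1;
    haplotypes, when present, is the phased n_variants x 2*n_samples binary
    matrix with columns (2i, 2i+1) belonging to sample i.
    """

    contig: str
    positions: np.ndarray          # 1-based POS, int64, strictly increasing
    genotypes: np.ndarray          # (n_variants, n_samples) int8
    sample_ids: list[str]
    quality: np.ndarray            # (n_variants,) float64
    haplotypes: np.ndarray | None = None   # (n_variants, 2*n_samples) int8
    biallelic: np.ndarray = field(default=None)  # bool mask
    is_snp: np.ndarray = field(default=None)     # bool mask

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.quality is None:
            self.quality = np.full(len(self.positions), np.inf)
        self.quality = np.asarray(self.quality, dtype=float)
        if self.biallelic is None:
            self.biallelic = np.ones(len(self.positions), dtype=bool)
        if self.is_snp is None:
            self.is_snp = np.ones(len(self.positions), dtype=bool)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions not strictly increasing on {self.contig}")

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take(self, index: np.ndarray) -> "VariantMatrix":
        """Row-subset (variants) by boolean mask or integer index."""
        return VariantMatrix(
            contig=self.contig,
            positions=self.positions[index],
            genotypes=self.genotypes[index],
            sample_ids=list(self.sample_ids),
            quality=self.quality[index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
            biallelic=self.biallelic[index],
            is_snp=self.is_snp[index],
        )

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None


@dataclass
class PopulationMap:
    """sample id -> population label, with label order preserved."""

    assignments: dict[str, str]
    populations: list[str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PopulationMap":
        assignments: dict[str, str] = {}
        populations: list[str] = []
        for sample, pop in pairs:
            if sample in assignments and assignments[sample] != pop:
                raise ValueError(
                    f"sample {sample!r} assigned to both "
                    f"{assignments[sample]!r} and {pop!r}"
                )
            assignments[sample] = pop
            if pop not in populations:
                populations.append(pop)
        return cls(assignments, populations)

    def samples(self, population: str) -> list[str]:
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return [s for s, p in self.assignments.items() if p == population]


@dataclass
class FilterSpec:
    """Variant-level filters: strict inequalities throughout."""

    min_call_rate: float = 0.9
    min_quality: float = 30.0
    adjacency_bp: int = 5
    biallelic_only: bool = True
    snps_only: bool = True
    adjacency_keep_first: bool = False  # alternative to removing both members

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0,1]")
        if self.adjacency_bp < 0:
            raise ValueError("adjacency_bp must be >= 0")


@dataclass
class GeneSet:
    """Gene records with 0-based half-open internal coordinates."""

    gene_ids: list[str]
    contigs: list[str]
    starts: np.ndarray
    ends: np.ndarray
    strands: list[str]

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_vcf(path: str | Path, samples: Sequence[str] | None = None) -> dict[str, VariantMatrix]:
    """Read a VCF 4.x file into one VariantMatrix per contig.

    Multi-allelic records and INDELs are retained but flagged (``biallelic``,
    ``is_snp``) for :func:`filter_variants` to act on. The haplotype matrix is
    populated only when every retained genotype on the contig is phased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if samples is not None:
        known = set(vcf.samples)
        for s in samples:
            if s not in known:
                raise KeyError(f"unknown sample {s!r} in {path}")
        vcf.set_samples(list(samples))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)

    per_contig: dict[str, dict[str, list]] = {}
    for v in vcf:
        rec = per_contig.setdefault(
            v.CHROM,
            {"pos": [], "qual": [], "gt": [], "hap": [], "phased": [], "bi": [], "snp": []},
        )
        gts = v.genotypes  # [[a0, a1, phased], ...]
        dosage = np.empty(n, dtype=np.int8)
        hap = np.empty(2 * n, dtype=np.int8)
        all_phased = True
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                dosage[i] = MISSING
                hap[2 * i] = hap[2 * i + 1] = MISSING
                all_phased = False
            else:
                dosage[i] = (a0 > 0) + (a1 > 0)
                hap[2 * i] = 1 if a0 > 0 else 0
                hap[2 * i + 1] = 1 if a1 > 0 else 0
                if not g[2]:
                    all_phased = False
        rec["pos"].append(v.POS)
        rec["qual"].append(v.QUAL if v.QUAL is not None else np.inf)
        rec["gt"].append(dosage)
        rec["hap"].append(hap)
        rec["phased"].append(all_phased)
        rec["bi"].append(len(v.ALT) == 1)
        rec["snp"].append(
            len(v.REF) == 1 and all(len(a) == 1 and a in "ACGT" for a in v.ALT)
        )

    out: dict[str, VariantMatrix] = {}
    for contig, rec in per_contig.items():
        phased_ok = bool(rec["phased"]) and all(rec["phased"])
        out[contig] = VariantMatrix(
            contig=contig,
            positions=np.array(rec["pos"], dtype=np.int64),
            genotypes=np.array(rec["gt"], dtype=np.int8),
            sample_ids=sample_ids,
            quality=np.array(rec["qual"], dtype=float),
            haplotypes=np.array(rec["hap"], dtype=np.int8) if phased_ok else None,
            biallelic=np.array(rec["bi"], dtype=bool),
            is_snp=np.array(rec["snp"], dtype=bool),
        )
    return out


def filter_variants(vm: VariantMatrix, spec: FilterSpec) -> VariantMatrix:
    """Apply biallelic/SNP, quality, call-rate and adjacency filters.

    Quality and call-rate thresholds are strict (> not >=). The adjacency
    rule runs last: by default BOTH members of any consecutive pair closer
    than ``adjacency_bp`` are removed, applied transitively along runs of
    clustered SNPs; ``adjacency_keep_first`` keeps the first of each run
    instead. Idempotent for a fixed spec.
    """
    keep = np.ones(vm.n_variants, dtype=bool)
    if spec.biallelic_only:
        keep &= vm.biallelic
    if spec.snps_only:
        keep &= vm.is_snp
    keep &= vm.quality > spec.min_quality
    call_rate = np.mean(vm.genotypes != MISSING, axis=1)
    keep &= call_rate > spec.min_call_rate

    sub = vm.take(keep)
    if spec.adjacency_bp > 0 and sub.n_variants > 1:
        gaps = np.diff(sub.positions)
        close = gaps < spec.adjacency_bp
        if spec.adjacency_keep_first:
            mask = np.ones(sub.n_variants, dtype=bool)
            # greedy left-to-right: drop any SNP too close to the last kept one
            last = sub.positions[0]
            for i in range(1, sub.n_variants):
                if sub.positions[i] - last < spec.adjacency_bp:
                    mask[i] = False
                else:
                    last = sub.positions[i]
        else:
            mask = np.ones(sub.n_variants, dtype=bool)
            mask[:-1] &= ~close
            mask[1:] &= ~close
        sub = sub.take(mask)
    return sub


def read_population_map(path: str | Path) -> PopulationMap:
    """Two-column whitespace-separated sample/population file."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            pairs.append((parts[0], parts[1]))
    return PopulationMap.from_pairs(pairs)


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """FAI-style file: first two columns are contig name and length."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            lengths[parts[0]] = int(parts[1])
    return lengths


def read_genes(path: str | Path) -> GeneSet:
    """Read gene annotations from BED or GFF3 (``gene`` features only).

    BED is already 0-based half-open; GFF3 1-based inclusive coordinates are
    converted to 0-based half-open.
    """
    path = Path(path)
    gene_ids: list[str] = []
    contigs: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if first:
                first = False
                if line.startswith("##gff-version"):
                    is_gff = True
                    continue
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if is_gff:
                if f[2].lower() != "gene":
                    continue
                start, end = int(f[3]), int(f[4])
                if start > end:
                    raise ValueError(f"{path}:{lineno}: start > end")
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("Name") or f"gene_{lineno}"
                gene_ids.append(gid)
                contigs.append(f[0])
                starts.append(start - 1)  # to 0-based half-open
                ends.append(end)
                strands.append(f[6] if len(f) > 6 else ".")
            else:
                start, end = int(f[1]), int(f[2])
                if start > end:
                    raise ValueError(f"{path}:{lineno}: start > end")
                gene_ids.append(f[3] if len(f) > 3 else f"gene_{lineno}")
                contigs.append(f[0])
                starts.append(start)
                ends.append(end)
                strands.append(f[5] if len(f) > 5 else ".")
    return GeneSet(
        gene_ids=gene_ids,
        contigs=contigs,
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        strands=strands,
    )


def write_bed(intervals, path: str | Path, values=None, names=None) -> None:
    """Write intervals as BED6 (0-based half-open; value in column 5).

    ``intervals`` is an iterable of objects with contig/start/end attributes
    or (contig, start, end) tuples.
    """
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if hasattr(iv, "contig"):
                contig, start, end = iv.contig, iv.start, iv.end
            else:
                contig, start, end = iv[0], iv[1], iv[2]
            name = names[i] if names is not None else f"iv{i}"
            value = values[i] if values is not None else 0.0
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{value:.6g}\t.\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str, float]]:
    """Read BED back as (contig, start, end, name, score) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            score = float(f[4]) if len(f) > 4 else 0.0
            out.append((f[0], int(f[1]), int(f[2]), name, score))
    return out


def write_vcf(
    vms: Sequence[VariantMatrix] | VariantMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write VariantMatrix objects as a minimal VCF 4.2 with GT fields.

    Phased pipes are emitted when a haplotype matrix is present, otherwise
    unphased slashes; REF/ALT are placeholder A/T alleles (the scan
    statistics are allele-label-free).
    """
    if isinstance(vms, VariantMatrix):
        vms = [vms]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for vm in vms:
            length = (contig_lengths or {}).get(vm.contig)
            if length is not None:
                fh.write(f"##contig=<ID={vm.contig},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={vm.contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vms[0].sample_ids)
            + "\n"
        )
        for vm in vms:
            phased = vm.haplotypes is not None
            sep = "|" if phased else "/"
            for k in range(vm.n_variants):
                fields = [
                    vm.contig, str(vm.positions[k]), ".", "A", "T",
                    "." if not np.isfinite(vm.quality[k]) else f"{vm.quality[k]:g}",
                    "PASS", ".", "GT",
                ]
                gts = []
                for i in range(vm.n_samples):
                    if phased:
                        a0, a1 = vm.haplotypes[k, 2 * i], vm.haplotypes[k, 2 * i + 1]
                        gts.append("." + sep + "." if a0 < 0 else f"{a0}{sep}{a1}")
                    else:
                        d = vm.genotypes[k, i]
                        if d < 0:
                            gts.append("./.")
                        else:
                            gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
                fh.write("\t".join(fields) + "\t" + "\t".join(gts) + "\n")
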