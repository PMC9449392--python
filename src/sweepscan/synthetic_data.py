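"""Forward Wright-Fisher simulator for a two-parents-plus-hybrid design.

Emulates the breeding structure the scan assumes: an ancestral population
split into two parental breeds that drift apart for ``split_gens``
generations, then a hybrid founded by drawing haplotypes from both parents
(``admix_prop`` from parent A) and closed-bred for ``admix_gens``
generations, optionally under a hard selective sweep at a known position.

The simulation is exact forward-in-time at desk scale: discrete
generations, multinomial resampling weighted by viability fitness
(1, 1+hs, 1+2s-like scheme 1/1+hs/1+s by sweep-site genotype), Poisson
recombination with uniform crossover positions, and infinite-sites Poisson
mutation with collision re-draw. Population sizes and per-bp rates are
scaled (small N, inflated mu and rho) so that per-site diversity 4*N*mu and
per-site scaled recombination match a realistic SNP density and LD decay at
megabase scale; see the package methods note.

The ancestral pool is initialised from the neutral equilibrium
site-frequency spectrum (derived-allele count i with probability
proportional to 1/i, carriers random) and then burned in for
``burnin_gens`` forward generations to establish linkage disequilibrium.

Everything is driven by one ``numpy.random.Generator`` seeded from
``SimConfig.seed``: identical seeds give bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sweepscan.core_io import PopulationMap, VariantMatrix, write_vcf


@dataclass
class SweepSpec:
    population: str = "H"        # "A", "B" or "H"
    position: int = 1_000_000    # bp, in [0, L)
    s: float = 0.1               # selection coefficient per beneficial allele copy
    h: float = 0.5               # dominance, used by the "additive" scheme only
    # "genic": multiplicative fitness (1+s)^copies, the classic sweep-theory
    # convention; "additive": 1, 1+h*s, 1+s.
    scheme: str = "genic"
    target_freq: float = 1.0     # stop once beneficial frequency reaches this
    max_gens: int = 5_000
    max_restarts: int = 500


@dataclass
class SimConfig:
    n_diploid: int = 100         # N per population
    length: int = 2_000_000      # L, bp
    mu: float = 2.5e-7           # per-bp per-generation (scaled; 4N*mu = 1e-4/site)
    rho: float = 2.5e-8          # per-bp per-generation (scaled; 4N*rho = 1e-5/site)
    burnin_gens: int = 100
    split_gens: int = 200
    admix_prop: float = 0.5      # parent-A fraction in hybrid founders
    admix_gens: int = 50         # closed-breeding drift of the hybrid breed
    n_sample: int = 10           # diploids sampled per population for output
    sweep: SweepSpec | None = None
    seed: int = 0
    contig: str = "chr1"
    pop_labels: tuple[str, str, str] = ("A", "B", "H")

    def __post_init__(self) -> None:
        if not 0.0 <= self.admix_prop <= 1.0:
            raise ValueError("admix_prop must be in [0,1]")
        if self.mu < 0 or self.rho < 0:
            raise ValueError("rates must be non-negative")
        if self.n_diploid < 2:
            raise ValueError("need at least 2 diploids")
        if self.sweep is not None and not 0 <= self.sweep.position < self.length:
            raise ValueError("sweep position outside [0, L)")


@dataclass
class SweepTruth:
    """Ground truth of the simulated sweep — the detection-power oracle."""

    population: str
    position: int
    interval: tuple[int, int]    # bp window around the swept site
    final_freq: float
    s: float
    h: float
    n_restarts: int
    gens_used: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class HaplotypePool:
    """One population's phased haplotypes over its segregating/fixed sites."""

    haps: np.ndarray        # (2N, n_sites) uint8
    positions: np.ndarray   # int64 bp, strictly increasing

    def copy(self) -> "HaplotypePool":
        return HaplotypePool(self.haps.copy(), self.positions.copy())

    @property
    def n_hap(self) -> int:
        return self.haps.shape[0]


def simulate_ancestral(
    config: SimConfig, n_burnin_gens: int | None = None, rng: np.random.Generator | None = None
) -> HaplotypePool:
    """Equilibrium-SFS draw followed by forward burn-in generations.

    Raises if mutation pressure is too weak to yield any segregating site.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_burnin_gens is None:
        n_burnin_gens = config.burnin_gens
    n_hap = 2 * config.n_diploid
    theta_locus = 4.0 * config.n_diploid * config.mu * config.length
    expected_s = theta_locus * np.sum(1.0 / np.arange(1, n_hap))
    n_sites = int(rng.poisson(expected_s)) if expected_s > 0 else 0
    if n_sites == 0:
        raise ValueError(
            "zero segregating sites in the ancestral pool; increase mu*L or N"
        )
    n_sites = min(n_sites, config.length)
    positions = np.sort(
        rng.choice(config.length, size=n_sites, replace=False)
    ).astype(np.int64)
    freq_weights = 1.0 / np.arange(1, n_hap)
    counts = rng.choice(np.arange(1, n_hap), size=n_sites, p=freq_weights / freq_weights.sum())
    haps = np.zeros((n_hap, n_sites), dtype=np.uint8)
    for j, c in enumerate(counts):
        carriers = rng.choice(n_hap, size=c, replace=False)
        haps[carriers, j] = 1
    pool = HaplotypePool(haps, positions)
    for _ in range(n_burnin_gens):
        pool = wf_generation(pool, config, rng)
        pool = cleanup(pool, keep_fixed=False)
    pool = cleanup(pool, keep_fixed=False)
    if pool.positions.size == 0:
        raise ValueError("all sites lost during burn-in; increase mu*L or N")
    return pool


def wf_generation(
    pool: HaplotypePool,
    config: SimConfig,
    rng: np.random.Generator,
    sweep_site: int | None = None,
    s: float = 0.0,
    h: float = 0.5,
    scheme: str = "genic",
) -> HaplotypePool:
    """One discrete Wright-Fisher generation.

    Each offspring haplotype samples a diploid parent (fitness-weighted when
    a sweep site is under selection), recombines the parent's two haplotypes
    with Poisson(rho*L) uniform crossovers, and Poisson(2N*mu*L) new
    mutations land on random offspring haplotypes at fresh positions.
    """
    haps, positions = pool.haps, pool.positions
    n_hap = haps.shape[0]
    if n_hap % 2:
        raise ValueError("haplotype count must be even")
    n_dip = n_hap // 2

    if sweep_site is not None and s != 0.0:
        dos = haps[0::2, sweep_site].astype(np.int64) + haps[1::2, sweep_site]
        if scheme == "genic":
            w = (1.0 + s) ** dos
        elif scheme == "additive":
            w = 1.0 + np.where(dos == 2, s, np.where(dos == 1, h * s, 0.0))
        else:
            raise ValueError(f"unknown selection scheme {scheme!r}")
        parents = rng.choice(n_dip, size=n_hap, p=w / w.sum())
    else:
        parents = rng.integers(0, n_dip, size=n_hap)

    a = haps[2 * parents]
    b = haps[2 * parents + 1]
    start = rng.integers(0, 2, size=n_hap)
    offspring = np.where(start[:, None] == 0, a, b)
    n_cx = rng.poisson(config.rho * config.length, size=n_hap)
    for k in np.flatnonzero(n_cx):
        cx = np.sort(rng.integers(0, config.length, size=n_cx[k]))
        seg = np.searchsorted(cx, positions, side="right")
        pick = (start[k] + seg) % 2
        offspring[k] = np.where(pick == 0, a[k], b[k])

    n_mut = rng.poisson(n_hap * config.mu * config.length)
    if n_mut:
        existing = set(positions.tolist())
        new_pos: list[int] = []
        while len(new_pos) < n_mut:
            cand = int(rng.integers(0, config.length))
            if cand not in existing:
                existing.add(cand)
                new_pos.append(cand)
        new_cols = np.zeros((n_hap, n_mut), dtype=np.uint8)
        new_cols[rng.integers(0, n_hap, size=n_mut), np.arange(n_mut)] = 1
        all_pos = np.concatenate([positions, np.array(new_pos, dtype=np.int64)])
        order = np.argsort(all_pos, kind="stable")
        positions = all_pos[order]
        offspring = np.concatenate([offspring, new_cols], axis=1)[:, order]
    return HaplotypePool(np.ascontiguousarray(offspring), positions)


def cleanup(pool: HaplotypePool, keep_fixed: bool = True) -> HaplotypePool:
    """Drop lost columns (and, during burn-in, fixed ones).

    After the parental split, sites fixed within one population must be kept
    — they are real frequency differences from the other populations; lost
    sites are indistinguishable from all-reference and can go.
    """
    counts = pool.haps.sum(axis=0)
    keep = counts > 0
    if not keep_fixed:
        keep &= counts < pool.n_hap
    return HaplotypePool(np.ascontiguousarray(pool.haps[:, keep]), pool.positions[keep])


def evolve(
    pool: HaplotypePool, gens: int, config: SimConfig, rng: np.random.Generator
) -> HaplotypePool:
    for _ in range(gens):
        pool = wf_generation(pool, config, rng)
        pool = cleanup(pool, keep_fixed=True)
    return pool


def _align_union(pools: list[HaplotypePool]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Expand each pool's matrix to the union of all positions (zero-fill)."""
    union = pools[0].positions
    for p in pools[1:]:
        union = np.union1d(union, p.positions)
    mats = []
    for p in pools:
        m = np.zeros((p.n_hap, len(union)), dtype=np.uint8)
        idx = np.searchsorted(union, p.positions)
        m[:, idx] = p.haps
        mats.append(m)
    return union, mats


def admix(
    pool_a: HaplotypePool,
    pool_b: HaplotypePool,
    admix_prop: float,
    admix_gens: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> HaplotypePool:
    """Found a hybrid population and let it drift.

    Each founder haplotype comes from parent A with probability
    ``admix_prop`` (a random haplotype of that parent), else from parent B;
    then ``admix_gens`` closed Wright-Fisher generations.
    """
    if pool_a.n_hap == 0 or pool_b.n_hap == 0:
        raise ValueError("empty parental population")
    union, (mat_a, mat_b) = _align_union([pool_a, pool_b])
    n_hap = 2 * config.n_diploid
    from_a = rng.random(n_hap) < admix_prop
    src_a = rng.integers(0, pool_a.n_hap, size=n_hap)
    src_b = rng.integers(0, pool_b.n_hap, size=n_hap)
    founders = np.where(from_a[:, None], mat_a[src_a], mat_b[src_b])
    pool = HaplotypePool(np.ascontiguousarray(founders.astype(np.uint8)), union.copy())
    pool = cleanup(pool, keep_fixed=True)
    return evolve(pool, admix_gens, config, rng)


def run_sweep_phase(
    pool: HaplotypePool,
    sweep: SweepSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[HaplotypePool, SweepTruth]:
    """Introduce a single-copy beneficial allele and drive it past target_freq.

    Trajectories that lose the allele restart from the saved entry state
    (restart count recorded in the truth object), so sweep datasets always
    contain a sweep.
    """
    base = pool.copy()
    pos = sweep.position
    while pos in set(base.positions.tolist()):
        pos += 1  # infinite-sites collision nudge
    n_restarts = 0
    while n_restarts <= sweep.max_restarts:
        cur = base.copy()
        ins = int(np.searchsorted(cur.positions, pos))
        col = np.zeros((cur.n_hap, 1), dtype=np.uint8)
        col[rng.integers(0, cur.n_hap), 0] = 1
        cur = HaplotypePool(
            np.ascontiguousarray(np.concatenate(
                [cur.haps[:, :ins], col, cur.haps[:, ins:]], axis=1)),
            np.insert(cur.positions, ins, pos),
        )
        gens = 0
        lost = False
        while gens < sweep.max_gens:
            site = int(np.searchsorted(cur.positions, pos))
            cur = wf_generation(cur, config, rng, sweep_site=site, s=sweep.s,
                                h=sweep.h, scheme=sweep.scheme)
            gens += 1
            site = int(np.searchsorted(cur.positions, pos))
            freq = float(cur.haps[:, site].sum()) / cur.n_hap
            if freq == 0.0:
                lost = True
                break
            if freq >= sweep.target_freq:
                truth = SweepTruth(
                    population=sweep.population,
                    position=pos,
                    interval=(max(0, pos - 50_000), min(config.length, pos + 50_000)),
                    final_freq=freq,
                    s=sweep.s,
                    h=sweep.h,
                    n_restarts=n_restarts,
                    gens_used=gens,
                )
                return cleanup(cur, keep_fixed=True), truth
            # periodically prune lost columns to bound matrix growth
            if gens % 20 == 0:
                cur = cleanup(cur, keep_fixed=True)
        if not lost:
            raise RuntimeError("sweep did not reach target frequency within max_gens")
        n_restarts += 1
    raise RuntimeError("sweep lost in every attempt; increase max_restarts or s")


def generate_matrices(
    config: SimConfig,
) -> tuple[VariantMatrix, PopulationMap, SweepTruth | None]:
    """Run the full design in memory and return pipeline-ready objects.

    The output VariantMatrix holds ``n_sample`` diploids per population
    (phased), restricted to sites segregating among the sampled individuals.
    """
    rng = np.random.default_rng(config.seed)
    ancestral = simulate_ancestral(config, config.burnin_gens, rng)
    pool_a = evolve(ancestral.copy(), config.split_gens, config, rng)
    pool_b = evolve(ancestral.copy(), config.split_gens, config, rng)

    truth: SweepTruth | None = None
    sweep = config.sweep
    lab_a, lab_b, lab_h = config.pop_labels
    if sweep is not None and sweep.population == lab_a:
        pool_a, truth = run_sweep_phase(pool_a, sweep, config, rng)
    if sweep is not None and sweep.population == lab_b:
        pool_b, truth = run_sweep_phase(pool_b, sweep, config, rng)

    if sweep is not None and sweep.population == lab_h:
        hybrid = admix(pool_a, pool_b, config.admix_prop, 0, config, rng)
        hybrid, truth = run_sweep_phase(hybrid, sweep, config, rng)
    else:
        hybrid = admix(pool_a, pool_b, config.admix_prop, config.admix_gens, config, rng)
    if sweep is not None and truth is None:
        raise ValueError(
            f"sweep population {sweep.population!r} not among {config.pop_labels}"
        )
    if truth is not None:
        truth.config = {
            "n_diploid": config.n_diploid, "length": config.length,
            "mu": config.mu, "rho": config.rho, "split_gens": config.split_gens,
            "admix_prop": config.admix_prop, "admix_gens": config.admix_gens,
            "seed": config.seed,
        }

    union, mats = _align_union([pool_a, pool_b, hybrid])
    n_s = config.n_sample
    sample_ids: list[str] = []
    sample_pops: list[tuple[str, str]] = []
    hap_blocks = []
    for label, mat in zip((lab_a, lab_b, lab_h), mats):
        n_dip = mat.shape[0] // 2
        if n_s > n_dip:
            raise ValueError("n_sample exceeds population size")
        chosen = rng.choice(n_dip, size=n_s, replace=False)
        cols = np.empty((mat.shape[1], 2 * n_s), dtype=np.int8)
        for k, ind in enumerate(chosen):
            cols[:, 2 * k] = mat[2 * ind]
            cols[:, 2 * k + 1] = mat[2 * ind + 1]
        hap_blocks.append(cols)
        for k in range(n_s):
            sid = f"{label}{k + 1:02d}"
            sample_ids.append(sid)
            sample_pops.append((sid, label))
    hap = np.concatenate(hap_blocks, axis=1)

    seg = (hap.sum(axis=1) > 0) & (hap.sum(axis=1) < hap.shape[1])
    hap = hap[seg]
    pos = union[seg]
    genotypes = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    vm = VariantMatrix(
        contig=config.contig,
        positions=pos + 1,  # to 1-based VCF POS
        genotypes=genotypes,
        sample_ids=sample_ids,
        quality=np.full(len(pos), 60.0),
        haplotypes=hap,
    )
    pmap = PopulationMap.from_pairs(sample_pops)
    return vm, pmap, truth


def generate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Write the complete pipeline input set to a directory.

    Produces ``sim.vcf`` (phased), ``popmap.tsv``, ``contigs.fai`` and
    ``truth.json`` (sweep runs only); returns the paths plus the truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vm, pmap, truth = generate_matrices(config)
    vcf_path = outdir / "sim.vcf"
    write_vcf(vm, vcf_path, contig_lengths={config.contig: config.length})
    popmap_path = outdir / "popmap.tsv"
    with open(popmap_path, "w") as fh:
        for sid in vm.sample_ids:
            fh.write(f"{sid}\t{pmap.assignments[sid]}\n")
    fai_path = outdir / "contigs.fai"
    with open(fai_path, "w") as fh:
        fh.write(f"{config.contig}\t{config.length}\n")
    paths = {"vcf": vcf_path, "popmap": popmap_path, "fai": fai_path}
    if truth is not None:
        truth_path = outdir / "truth.json"
        truth_path.write_text(truth.to_json())
        paths["truth"] = truth_path
    paths["truth_obj"] = truth
    return paths
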