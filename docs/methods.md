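# Methods

This note documents the statistical procedures, the simulator that
generates the test conditions, the numerical conventions, and the design
choices that were genuinely open — together with what the passing tests do
and do not demonstrate about real data.

## Scan statistics

**Windows.** All scan statistics live on half-step sliding windows
(default 100 kb advancing by 50 kb), built per contig from position 0;
trailing partial windows are emitted and flagged rather than dropped, so
the window universe always covers the contig. Windows with fewer than
`min_snps` (default 10) informative SNPs are set to missing before any
Z-transformation; missing windows are never selected as candidates.

**Pooled heterozygosity.** `Hp = 2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)²` with the
major/minor allele counts summed over the window's SNPs. Counts are derived
from genotypes (the data are individual genomes, not read pools); missing
genotypes are excluded per site, with no imputation. `Hp ∈ [0, 0.5]` and is
invariant to which allele is labelled major at any single SNP.

**FST.** The per-SNP two-population estimator is Weir & Cockerham (1984),
`θ̂ = a/(a+b+c)` from the among/within variance components with observed
heterozygote frequencies; sites monomorphic across both populations or with
missing data in either are undefined and excluded. The window value is the
arithmetic mean of defined per-SNP estimates; a ratio-of-sums variant
(`Σa/Σ(a+b+c)`) and Hudson's estimator are available as options. The
ratio-of-sums form is the one with (near-)zero expectation under a random
split of one population; the per-SNP ratio has a small negative null bias
that averaging does not remove — relevant when interpreting genome-wide
mean FST, irrelevant for outlier ranking.

**Nucleotide diversity and its ratio.** `θπ` per window is
`Σ_sites 2p̂(1−p̂)·n/(n−1)` divided by the window length in bp (`n` = number
of non-missing alleles at the site), which equals the mean pairwise
difference per bp. The log2 ratio between two populations is missing (never
±inf) when the denominator is zero; a pseudocount option exists for very
small simulated windows. The direction of the ratio is explicit
configuration: the pipeline default puts the *reference* population in the
numerator so that the high tail flags windows of unusually low diversity in
the focal (hybrid) population, which is the sweep-in-focal logic; the
labelling with the focal population in the numerator is available since
published analyses have used both conventions and the printed threshold
(`log2 > 2`) does not itself disambiguate the direction.

**Z-transformation.** Genome-wide (all contigs jointly), population
(divide-by-N) standard deviation, missing propagates. Per-chromosome
standardisation was rejected: the Manhattan-style scan is a genome-wide
ranking exercise.

**EHH / iHH / XP-EHH.** `EHH(x) = Σ_h C(c_h,2)/C(n,2)` over the counts of
distinct extended haplotypes from the core out to distance x. EHH is
computed over *all* haplotypes of a population — `EHH(0)` is the core-site
homozygosity — rather than per core allele, because in the cross-population
use a core polymorphic in one population may be fixed in the other;
per-allele curves are available for diagnostics. Extension stops when EHH
drops below 0.05 or an inter-SNP gap exceeds 200 kb (both configurable;
common practice). iHH is the trapezoidal integral of EHH against physical
distance (no genetic map is used), summed over both directions; a side with
no flanking SNP contributes zero. XP-EHH is the *unstandardized*
`ln(iHH_A/iHH_B)`: the windowed cut-off 0.7 used for candidate extraction
is far below the |2| typical of normalized per-SNP XP-EHH, so the literal
threshold semantics require the raw ratio; a genome-wide mean/sd
normalisation is provided behind a flag. Positive values mean longer
haplotypes in the first-named (numerator) population, and the convention is
echoed in every report header. The implementation sorts haplotypes once per
core/direction and replays boundary-appearance events, which is exactly
equal (tested) to the O(n²L) pairwise-identity definition.

**Candidate extraction and combination.** Thresholds are strict
inequalities exactly as printed (`<`, `>`). In `percentile` mode each
track's cut-off is replaced by the empirical tail percentile of its own
values — the appropriate calibration at simulated genome sizes where ±4 sd
outliers cannot exist among ~40 windows. Candidate sets from the same
statistic family (e.g. FST against two different references) are unioned
before combination; windows present in ≥ `min_methods` (default 2) family
sets form the combined set, with supporting methods recorded as provenance.
Gene assignment extends each candidate window by a symmetric 50-kb flank
(clipped at zero, strand ignored) and reports any gene with ≥1 bp overlap
of the half-open intervals, deduplicated with merged provenance. Evidence
can alternatively be combined at the gene level after per-track mapping;
window-level-first is the default.

## Variant filtering

Only biallelic SNPs with call rate > 0.9 and quality > 30 (strict
inequalities) enter the pipeline; INDELs and multi-allelic records are
parsed but dropped. The adjacency rule then removes *both* members of any
consecutive SNP pair closer than 5 bp, applied transitively along runs of
clustered SNPs — the conservative reading of "not keeping two adjacent
SNPs"; keeping the first of each run is a config switch. Coordinates are
0-based half-open internally; VCF/GFF3 ingestion converts, and user-facing
positions are 1-based.

Phasing is an input requirement for the haplotype statistics: the package
does not phase, and the simulator emits phased VCFs.

## Population structure

Pairwise distance is 1 − IBS from dosages (`d = mean |g_i − g_j| / 2`); the
distance actually fed to tree building in the original workflow is not
recorded anywhere, so this choice is flagged in the report header and
swappable. Neighbour joining is Saitou–Nei via scikit-bio, exact on
additive matrices (verified against 100 random additive trees,
Robinson–Foulds 0, path lengths to 1e−9); negative branch lengths are
clamped to zero. PCA centres each SNP by `2p̂` and scales by
`√(p̂(1−p̂))` (Patterson normalisation), mean-imputes missing dosages,
drops monomorphic SNPs, and reports eigenvector-times-`√eigenvalue`
coordinates; Tracy–Widom significance is out of scope. LD decay filters
SNPs (MAF > 0.05 strictly; per-SNP heterozygote fraction ≤ 0.9; missingness
≤ 0.1 — the PopLDdecay-style semantics of those two caps), computes r² from
phased haplotypes (equivalently the squared correlation of the binary
haplotype vectors) or from dosage correlation when unphased, and averages
in distance bins (1 kb default, 1 Mb maximum distance).

## The simulator and its scaling

Forward Wright–Fisher, chosen over a coalescent because selection and
admixture are then exact by construction at desk scale. Discrete
generations; fitness-weighted parent sampling; Poisson(ρL) crossovers at
uniform positions per transmitted haplotype; Poisson(2NμL) new mutations
per generation at fresh positions (infinite sites, collision re-draw).
The ancestral pool is initialised from the neutral equilibrium frequency
spectrum (derived count `i` with probability ∝ 1/i) and burned in for
`burnin_gens` (default 100) forward generations to build linkage
disequilibrium; the equilibrium-heterozygosity oracle test uses a small-N
configuration where the burn-in genuinely equilibrates.

Default conditions: N = 100 diploids per population, L = 2 Mb,
μ = 2.5e−7/bp/gen so that per-site diversity 4Nμ = 1e−4 gives a realistic
SNP density (~1 SNP / 1.2 kb), parental split 200 generations,
hybrid founded with `admix_prop` = 0.5 and closed-bred for 50 generations,
10 diploids sampled per population (matching typical resequencing panel
sizes). Recombination is deliberately scaled *less* than mutation:
ρ = 2.5e−8/bp/gen (4Nρ = 1e−5/site), because the physical footprint of a
hard sweep scales as 1/(ρ·T_fix); full λ-scaling of ρ would shrink the
footprint of a desk-scale sweep far below the 100-kb window the method
assumes, misrepresenting the study design rather than miniaturising it.

Selection uses genic (multiplicative) fitness `(1+s)^copies` — the classic
sweep-theory convention in which `s` is the advantage per allele copy — with
an additive `1 / 1+hs / 1+s` scheme available. Sweeps start from a single
copy; trajectories that lose the allele are restarted from the saved entry
state (restart count recorded in the truth object), and the swept
population's drift phase runs under selection until the beneficial
frequency reaches `target_freq` (default 1.0, i.e. fixation — an incomplete
sweep stopped at intermediate frequency *raises* pooled heterozygosity at
linked sites and is undetectable by diversity statistics). The truth record
stores the position, a ±50-kb interval around it, the final frequency and
the generations used, and is the oracle for detection power.

Structure-layer experiments use a deeper hybrid drift phase
(`admix_gens` = 200) over two 1-Mb contigs (multi-contig datasets are
concatenations of independent runs, emulating independent chromosomes):
breed-level clustering in an NJ tree requires the hybrid breed's own drift
to exceed within-breed noise, which real breeds accumulate over decades of
closed breeding, and single short contigs give individual hybrids too much
ancestry variance to cluster.

## What desk scale does and does not show

The simulations compress time: at N = 100 and s = 0.1 the conditional
fixation time (~85–130 generations) is ~0.2–0.3 of 4N generations, so a
swept window retains residual diversity (new mutation plus recombination
leak during the sweep) of the same order as the genome-wide *drift minimum*
across ~40 windows — whereas in a real genome T_fix/4N ≈ 1e−3 and a
completed sweep is orders of magnitude below any neutral window. Measured
consequences, reported honestly by `scripts/acceptance.py` rather than
hidden: sweep-recovery power at the 1st/99th-percentile thresholds is
~25–45% per-window (the swept *region* is usually flagged, but the most
extreme single window is often a neighbouring or drift window), and the
≥2-method combined set is non-empty in most neutral replicates because
pooled heterozygosity and the θπ-ratio are both monotone in focal-window
diversity, so their percentile tails coincide on the same drift-extreme
window — a tail dependence that is intrinsic to combining correlated
statistics and much milder in real genomes, where per-window genealogical
variance is smoothed over ~40× more recombination. Passing the oracle,
property, structure and determinism checks therefore demonstrates
correctness of the estimators and the pipeline; the power/specificity
numbers characterise the desk-scale regime, not the method's behaviour on
real resequencing data.

## Numerical conventions

Missing values are NaN throughout and propagate (never selected, never
±inf). Z-transformation refuses tracks with < 2 finite values or zero
spread, naming the track. NJ ties follow scikit-bio's lowest-index rule.
The EHH event replay uses exact integer pair counts, so fast-vs-oracle
agreement is exact, not approximate. All randomness flows from a single
`numpy.random.Generator` seeded from the run seed; dataset files and
statistic TSVs are byte-identical across reruns with the same seed (fixed
float formatting, sorted iteration orders).
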