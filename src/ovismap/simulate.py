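"""Gene-dropping simulator for wild-pedigree linkage-map studies.

The generator emulates the structure of the two pedigreed bighorn sheep
mapping populations this package was designed around: multigenerational
pedigrees with polygynous sires (e.g. 42 sires averaging 4.4 +/- 3.5
offspring each), microsatellite panels of 2-12 alleles with ~95% typing
success, and sex-specific true maps whose genome-wide female:male length
ratio is ~1.12 while interval-level dimorphism follows a smooth quadratic
profile along the centromere (0) -> telomere (1) axis.

Crossovers are simulated independently per interval with marginal
recombination probability equal to the inverse-Kosambi transform of the
transmitting parent's sex-specific interval length.  Marginal two-point
recombination fractions therefore match the true map exactly, but
multi-interval coincidence probabilities carry no interference — the
quantity downstream two-point and fixed-order estimation consumes is the
marginal theta, which is what the simulator controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .mapping import kosambi_inverse
from .pedigree import FEMALE, MALE, GenotypeTable, Individual, Pedigree


@dataclass
class PopulationConfig:
    """Pedigree structure of one mapping population.

    ``n_sires`` is the total number of sires over the whole pedigree,
    divided evenly across the offspring generations.  Sibship sizes are
    drawn from a zero-truncated negative binomial matched to the given
    mean/SD (Poisson when SD^2 <= mean, constant when SD = 0).  Dams are
    assigned by drawing dam sibship sizes until the generation's offspring
    are covered, so the realised number of dams follows from the dam
    sibship mean.
    """

    name: str = "NBR"
    n_founders: int = 80
    n_generations: int = 3
    n_sires: int = 42
    sire_mean: float = 4.4
    sire_sd: float = 3.5
    dam_mean: float = 3.4
    dam_sd: float = 2.1


@dataclass
class SimulationConfig:
    """Study-level configuration: true map, marker panel and noise model."""

    populations: tuple[PopulationConfig, ...] = (
        PopulationConfig("NBR", n_founders=80, n_generations=3, n_sires=42,
                         sire_mean=4.4, sire_sd=3.5, dam_mean=3.4, dam_sd=2.1),
        PopulationConfig("RM", n_founders=90, n_generations=3, n_sires=43,
                         sire_mean=3.9, sire_sd=3.3, dam_mean=2.4, dam_sd=1.3),
    )
    n_chromosomes: int = 4
    markers_per_chromosome: int = 8
    mean_interval_cm: float = 14.3
    sd_interval_cm: float = 9.1
    #: true inter-marker spacing is clipped to this range: mapping panels
    #: are selected for coverage, markers closer than a few cM collapse to
    #: effectively co-located positions whose order two-point data cannot
    #: resolve, and gaps beyond ~45 cM exceed two-point linkage range (maps
    #: are broken at > 50 cM sex-averaged intervals downstream)
    min_interval_cm: float = 4.0
    max_interval_cm: float = 45.0
    female_male_ratio: float = 1.12
    #: dimorphism profile s(x) = b0 + b1 x + b2 x^2 of interval midpoint
    #: position x in [0, 1]; s > 0 female-longer (SDI convention).  Concave
    #: (female bias peaks mid-chromosome, weakest near centromere and
    #: telomere) with mean ~0.125, matching the genome-wide 1.12 ratio
    sdi_quadratic: tuple[float, float, float] = (0.05, 0.45, -0.45)
    min_alleles: int = 2
    max_alleles: int = 12
    typing_success: float = 0.95
    error_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        for rate in (self.typing_success, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must be in [0, 1], got {rate}")
        if self.female_male_ratio <= 0:
            raise ValueError("female:male ratio must be positive")
        for p in self.populations:
            if p.n_founders < 2:
                raise ValueError(f"population {p.name}: need >= 2 founders")
            if p.n_generations < 2:
                raise ValueError(f"population {p.name}: need >= 2 generations")


# ---------------------------------------------------------------------------
# true maps


@dataclass
class TrueMap:
    """Sex-specific true marker positions (cM); the centromere sits at
    position 0 of every chromosome (acrocentric convention) and the female
    and male orders are identical by construction."""

    chromosomes: list[str]
    markers: dict[str, list[str]]          # chromosome -> ordered labels
    pos_f: dict[str, float]
    pos_m: dict[str, float]

    def all_markers(self) -> list[str]:
        return [m for c in self.chromosomes for m in self.markers[c]]

    def intervals(self, chrom: str, which: str = "f") -> np.ndarray:
        pos = self.pos_f if which == "f" else self.pos_m
        ms = self.markers[chrom]
        return np.diff([pos[m] for m in ms])

    def length(self, which: str = "f") -> float:
        return float(sum(self.intervals(c, which).sum()
                         for c in self.chromosomes))

    def pos_avg(self, marker: str) -> float:
        return 0.5 * (self.pos_f[marker] + self.pos_m[marker])


def _dimorphism_ratio(s: float) -> float:
    """female/male length ratio implied by an SDI value s (signed
    (max/min) - 1, positive female-larger)."""
    return 1.0 + s if s >= 0 else 1.0 / (1.0 - s)


def make_true_map(config: SimulationConfig,
                  rng: np.random.Generator) -> TrueMap:
    """Draw a sex-specific true map.

    Sex-averaged interval lengths are gamma-distributed around the
    configured mean/SD; the female:male split per interval follows the
    quadratic dimorphism profile of the interval's relative position, and
    the female map is then rescaled so the genome-wide female:male ratio
    equals ``female_male_ratio`` exactly (total sex-averaged length is
    preserved).
    """
    b0, b1, b2 = config.sdi_quadratic
    chromosomes = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    markers: dict[str, list[str]] = {}
    f_parts: dict[str, np.ndarray] = {}
    m_parts: dict[str, np.ndarray] = {}
    mean, sd = config.mean_interval_cm, config.sd_interval_cm
    shape = (mean / sd) ** 2 if sd > 0 else None
    for c, chrom in enumerate(chromosomes):
        k = config.markers_per_chromosome
        markers[chrom] = [f"C{c + 1}M{j + 1:02d}" for j in range(k)]
        if shape is None:
            lens = np.full(k - 1, mean)
        else:
            lens = rng.gamma(shape, mean / shape, size=k - 1)
        lens = np.clip(lens, config.min_interval_cm, config.max_interval_cm)
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        x = (cum[:-1] + cum[1:]) / (2.0 * cum[-1])  # midpoint, 0=centromere
        s = b0 + b1 * x + b2 * x ** 2
        ratio = np.array([_dimorphism_ratio(v) for v in s])
        f_parts[chrom] = 2.0 * lens * ratio / (1.0 + ratio)
        m_parts[chrom] = 2.0 * lens / (1.0 + ratio)
    tot_f = sum(v.sum() for v in f_parts.values())
    tot_m = sum(v.sum() for v in m_parts.values())
    c_f = config.female_male_ratio * tot_m / tot_f
    norm = (tot_f + tot_m) / (c_f * tot_f + tot_m)  # keep sex-averaged total
    pos_f: dict[str, float] = {}
    pos_m: dict[str, float] = {}
    for chrom in chromosomes:
        pf = np.concatenate([[0.0], np.cumsum(f_parts[chrom] * c_f * norm)])
        pm = np.concatenate([[0.0], np.cumsum(m_parts[chrom] * norm)])
        for m, a, b in zip(markers[chrom], pf, pm):
            pos_f[m] = float(a)
            pos_m[m] = float(b)
    return TrueMap(chromosomes, markers, pos_f, pos_m)


def draw_allele_frequencies(true_map: TrueMap, config: SimulationConfig,
                            rng: np.random.Generator
                            ) -> dict[str, dict[str, np.ndarray]]:
    """Founder allele frequencies per population per marker.

    Allele counts are drawn once per marker (shared allele pool across
    populations); frequencies are drawn per population from a flat
    Dirichlet, so populations share alleles but differ in diversity.
    """
    freqs: dict[str, dict[str, np.ndarray]] = {p.name: {}
                                               for p in config.populations}
    for marker in true_map.all_markers():
        k = int(rng.integers(config.min_alleles, config.max_alleles + 1))
        for pop in config.populations:
            freqs[pop.name][marker] = rng.dirichlet(np.ones(k))
    return freqs


# ---------------------------------------------------------------------------
# pedigree simulation


def _sibship_sizes(n: int, mean: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """``n`` zero-truncated sibship sizes with the requested moments."""
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    if sd <= 0:
        return np.full(n, max(1, round(mean)), dtype=np.int64)
    var = sd * sd

    def draw(size: int) -> np.ndarray:
        if var <= mean:
            return rng.poisson(mean, size=size)
        r = mean * mean / (var - mean)
        p = mean / var
        return rng.negative_binomial(r, p, size=size)

    out = draw(n)
    for _ in range(1000):
        zero = out == 0
        if not zero.any():
            break
        out[zero] = draw(int(zero.sum()))
    out[out == 0] = 1
    return out.astype(np.int64)


def simulate_pedigree(pop: PopulationConfig, rng: np.random.Generator,
                      population: str | None = None) -> Pedigree:
    """Simulate one multigenerational population pedigree.

    Founders (generation 0) are half male, half female.  Each offspring
    generation takes its sires and dams from earlier generations without
    reuse, so per-parent offspring counts follow the configured sibship
    distributions.
    """
    if pop.n_founders < 2:
        raise ValueError("need at least 2 founders")
    name = population or pop.name
    inds: list[Individual] = []
    males: list[str] = []
    females: list[str] = []
    for i in range(pop.n_founders):
        sex = MALE if i < (pop.n_founders + 1) // 2 else FEMALE
        iid = f"{name}_G0_{i:04d}"
        inds.append(Individual(iid, None, None, sex, name))
        (males if sex == MALE else females).append(iid)
    used: set[str] = set()
    n_off_gens = pop.n_generations - 1
    base = pop.n_sires // n_off_gens
    sires_per_gen = [base + (1 if g < pop.n_sires % n_off_gens else 0)
                     for g in range(n_off_gens)]
    for g in range(1, pop.n_generations):
        avail_m = [m for m in males if m not in used]
        avail_f = [f for f in females if f not in used]
        n_sires = min(sires_per_gen[g - 1], len(avail_m))
        sires = [avail_m[i] for i in
                 sorted(rng.choice(len(avail_m), size=n_sires, replace=False))]
        used.update(sires)
        sizes = _sibship_sizes(n_sires, pop.sire_mean, pop.sire_sd, rng)
        sire_of: list[str] = []
        for s, k in zip(sires, sizes):
            sire_of.extend([s] * int(k))
        # dams cover the offspring pool with their own sibship sizes
        dam_of: list[str] = []
        while len(dam_of) < len(sire_of) and len(used & set(avail_f)) < len(avail_f):
            remaining = [f for f in avail_f if f not in used]
            if not remaining:
                break
            dam = remaining[int(rng.integers(len(remaining)))]
            used.add(dam)
            k = int(_sibship_sizes(1, pop.dam_mean, pop.dam_sd, rng)[0])
            dam_of.extend([dam] * k)
        if len(dam_of) < len(sire_of):  # ran out of dams: truncate sibships
            sire_of = sire_of[:len(dam_of)]
        dam_of = dam_of[:len(sire_of)]
        order = rng.permutation(len(sire_of))
        for j, idx in enumerate(order):
            sex = MALE if rng.random() < 0.5 else FEMALE
            iid = f"{name}_G{g}_{j:04d}"
            inds.append(Individual(iid, sire_of[idx], dam_of[idx], sex, name))
            (males if sex == MALE else females).append(iid)
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# gene dropping


@dataclass
class TruthRecord:
    """Hidden simulation truth: grandparental origin (0 = from the parent's
    sire, 1 = from the parent's dam) of every transmitted allele, keyed by
    (parent_id, offspring_id) -> {marker: origin}."""

    origins: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)


def drop_genotypes(pedigree: Pedigree, true_map: TrueMap,
                   config: SimulationConfig, rng: np.random.Generator,
                   freqs: dict[str, dict[str, np.ndarray]] | None = None
                   ) -> tuple[GenotypeTable, TruthRecord]:
    """Drop founder haplotypes down the pedigree.

    Each gamete picks a random starting strand per chromosome, then
    recombines between adjacent markers independently with probability
    theta = inverse-Kosambi of the transmitting parent's sex-specific
    interval length.  The truth record keeps each transmission's
    grandparental origins for oracle tests.
    """
    if freqs is None:
        freqs = draw_allele_frequencies(true_map, config, rng)
    all_markers = true_map.all_markers()
    for pop_name, per_marker in freqs.items():
        missing = [m for m in all_markers if m not in per_marker]
        if missing:
            raise ValueError(f"population {pop_name}: no founder frequencies "
                             f"for markers {missing[:3]}")
    midx = {m: i for i, m in enumerate(all_markers)}
    # per-chromosome marker index ranges and sex-specific interval thetas
    chrom_cols = {c: np.array([midx[m] for m in true_map.markers[c]])
                  for c in true_map.chromosomes}
    theta = {}
    for c in true_map.chromosomes:
        theta[(c, FEMALE)] = np.array([kosambi_inverse(d)
                                       for d in true_map.intervals(c, "f")])
        theta[(c, MALE)] = np.array([kosambi_inverse(d)
                                     for d in true_map.intervals(c, "m")])

    # topological order: founders first, then by generation of definition
    order: list[Individual] = []
    placed: set[str] = set()
    pending = list(pedigree)
    while pending:
        rest = []
        for ind in pending:
            ok = all(p is None or p in placed
                     for p in (ind.sire_id, ind.dam_id))
            if ok:
                order.append(ind)
                placed.add(ind.id)
            else:
                rest.append(ind)
        if len(rest) == len(pending):
            raise ValueError("pedigree is not acyclic")
        pending = rest

    n_mark = len(all_markers)
    haplo: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    truth = TruthRecord()

    # founder haplotypes drawn in bulk, per population per marker
    founders_by_pop: dict[str, list[str]] = {}
    for ind in order:
        if ind.sire_id is None and ind.dam_id is None:
            founders_by_pop.setdefault(ind.population, []).append(ind.id)
    founder_pool: dict[str, np.ndarray] = {}
    for pop_name, ids in sorted(founders_by_pop.items()):
        mat = np.empty((2 * len(ids), n_mark), dtype=np.int64)
        for m in all_markers:
            p = freqs[pop_name][m]
            # alleles are labelled 1..k (0 is the missing sentinel in files)
            mat[:, midx[m]] = rng.choice(len(p), size=2 * len(ids), p=p) + 1
        founder_pool[pop_name] = mat
        for i, iid in enumerate(ids):
            haplo[iid] = (mat[2 * i], mat[2 * i + 1])

    def founder_haplotype(pop: str) -> np.ndarray:
        h = np.empty(n_mark, dtype=np.int64)
        for m in all_markers:
            p = freqs[pop][m]
            h[midx[m]] = rng.choice(len(p), p=p) + 1
        return h

    def make_gamete(parent: Individual) -> tuple[np.ndarray, np.ndarray]:
        """(allele vector, origin vector) of one gamete from ``parent``."""
        hp, hm = haplo[parent.id]
        sex = parent.sex if parent.sex in (FEMALE, MALE) else \
            (FEMALE if rng.random() < 0.5 else MALE)
        origin = np.empty(n_mark, dtype=np.int8)
        for c in true_map.chromosomes:
            cols = chrom_cols[c]
            th = theta[(c, sex)]
            strand = np.empty(len(cols), dtype=np.int8)
            strand[0] = rng.integers(2)
            if len(cols) > 1:
                switch = rng.random(len(th)) < th
                strand[1:] = switch
                strand = np.bitwise_xor.accumulate(strand)
            origin[cols] = strand
        gamete = np.where(origin == 0, hp, hm)
        return gamete, origin

    for ind in order:
        if ind.sire_id is None and ind.dam_id is None:
            continue  # founder haplotypes pre-drawn above
        gametes = []
        for pid in (ind.sire_id, ind.dam_id):
            if pid is None:
                gametes.append((founder_haplotype(ind.population), None))
                continue
            parent = pedigree.individuals[pid]
            g, orig = make_gamete(parent)
            truth.origins[(pid, ind.id)] = {
                m: int(orig[midx[m]]) for m in all_markers}
            gametes.append((g, orig))
        haplo[ind.id] = (gametes[0][0], gametes[1][0])

    table = GenotypeTable(all_markers)
    for ind in order:
        hp, hm = haplo[ind.id]
        for m in all_markers:
            table.set(ind.id, m, (int(hp[midx[m]]), int(hm[midx[m]])))
    return table, truth


def degrade(genotypes: GenotypeTable, config: SimulationConfig,
            rng: np.random.Generator) -> GenotypeTable:
    """Apply missingness and genotyping error.

    Calls go missing independently at rate 1 - typing_success; surviving
    calls are replaced, at the configured error rate, by a random genotype
    drawn from the marker's observed allele pool.
    """
    if config.typing_success >= 1.0 and config.error_rate <= 0.0:
        return genotypes.copy()
    pools: dict[str, set] = {m: set() for m in genotypes.markers}
    for (_ind, marker), gt in genotypes.calls.items():
        pools[marker].update(gt)
    pools = {m: sorted(v) for m, v in pools.items()}
    table = GenotypeTable(genotypes.markers)
    miss = 1.0 - config.typing_success
    for (ind, marker), gt in sorted(genotypes.calls.items()):
        if miss > 0 and rng.random() < miss:
            continue
        if config.error_rate > 0 and rng.random() < config.error_rate:
            pool = pools[marker]
            gt = (pool[int(rng.integers(len(pool)))],
                  pool[int(rng.integers(len(pool)))])
        table.set(ind, marker, gt)
    return table


# ---------------------------------------------------------------------------
# study-level convenience


@dataclass
class StudyData:
    """One simulated mapping study: merged pedigree and genotypes for all
    populations, plus the hidden truth."""

    config: SimulationConfig
    true_map: TrueMap
    pedigree: Pedigree
    genotypes: GenotypeTable
    clean_genotypes: GenotypeTable
    truth: TruthRecord


def simulate_study(config: SimulationConfig,
                   seed: int | None = None) -> StudyData:
    """Simulate the full study: true map, per-population pedigrees, gene
    dropping and degradation.  Deterministic given config + seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    true_map = make_true_map(config, rng)
    freqs = draw_allele_frequencies(true_map, config, rng)
    all_inds: list[Individual] = []
    for pop in config.populations:
        ped = simulate_pedigree(pop, rng)
        all_inds.extend(ped)
    pedigree = Pedigree(all_inds)
    clean, truth = drop_genotypes(pedigree, true_map, config, rng, freqs)
    observed = degrade(clean, config, rng)
    return StudyData(config, true_map, pedigree, observed, clean, truth)


def recovery_study_config(n_sires: int = 500, seed: int = 0,
                          **overrides) -> SimulationConfig:
    """Configuration of the parameter-recovery study: two large populations
    (same sibship moments as the field pedigrees, more sires) over 4
    chromosomes x 8 markers, sized so every marker has well over 200
    informative meioses and adjacent intervals have enough meioses per sex
    for stable sex-specific estimates."""
    founders = int(math.ceil(n_sires / 2 * 4.4 / 2.0 / 10) * 10 + n_sires)
    pops = (
        PopulationConfig("P1", n_founders=founders, n_generations=3,
                         n_sires=n_sires, sire_mean=4.4, sire_sd=3.5,
                         dam_mean=3.4, dam_sd=2.1),
        PopulationConfig("P2", n_founders=founders, n_generations=3,
                         n_sires=n_sires, sire_mean=3.9, sire_sd=3.3,
                         dam_mean=2.4, dam_sd=1.3),
    )
    cfg = SimulationConfig(populations=pops, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
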