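"""Linkage-map construction from phased meioses.

The pipeline implemented here follows the classic microsatellite workflow:

1. :func:`phase_meioses` turns Mendelian-clean pedigree genotypes into a
   :class:`MeiosisPanel` of parent->offspring transmissions.  Wherever the
   transmitted allele is resolvable and the parent's own parental origin of
   that allele is resolvable from grandparental genotypes, the transmission
   carries a grandparental-origin indicator (phase-known).  Otherwise the
   transmitted allele is recorded with a phase-uncertainty flag.
2. :func:`twopoint` estimates the recombination fraction theta and LOD score
   for a marker pair by maximum likelihood.  Phase-known meioses contribute
   the binomial factor theta^R (1-theta)^(N-R); each phase-uncertain parent
   contributes an equal-prior two-phase mixture over its offspring.
3. :func:`form_linkage_groups` partitions markers into linkage groups by
   single-linkage clustering at a pairwise LOD threshold (default > 4), and
   :func:`assign_stragglers` applies reference-map rescue rules.
4. :func:`order_build` seeds each group with its most informative high-LOD
   pair and inserts markers greedily under a descending LOD ladder;
   :func:`refine_flips` polishes the order by exhaustive permutation of
   sliding windows (window 5 by default).
5. :func:`flag_double_recombinants` screens origin strings for isolated
   double recombinants within a short map span.
6. :func:`estimate_map` fixes the order and estimates per-interval
   sex-averaged, female and male recombination fractions, transformed to
   centimorgans with the Kosambi map function; :func:`split_long_intervals`
   breaks groups at sex-averaged gaps above 50 cM.

The multipoint likelihood is a phased-meiosis approximation: within each
meiosis, recombination events are scored between consecutive *informative*
markers and the event is attributed once to that nearest-informative-flank
pair (no fractional allocation across spanned intervals).  The order
likelihood is the sum over observed flank pairs of the profile (theta
maximised per pair) log10-likelihood.  This is exact for fully informative
meioses and a documented approximation otherwise; it is not the full
Elston-Stewart pedigree likelihood of CRI-MAP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .pedigree import (FEMALE, MALE, UNKNOWN, GenotypeTable, Pedigree,
                       transmitted_allele, _transmissions)

LOG10 = math.log(10.0)
#: theta estimates this close to 0.5 are reported as unlinked (undefined cM)
THETA_UNLINKED = 0.5 - 1e-6
#: numerical tolerance of the golden-section theta maximiser
THETA_TOL = 1e-6


# ---------------------------------------------------------------------------
# Kosambi map function


def kosambi(theta: float) -> float:
    """Map a recombination fraction to centimorgans, d = 25 ln((1+2t)/(1-2t))."""
    if not 0.0 <= theta < 0.5:
        raise ValueError(f"theta must be in [0, 0.5), got {theta}")
    return 25.0 * math.log((1.0 + 2.0 * theta) / (1.0 - 2.0 * theta))


def kosambi_inverse(cm: float) -> float:
    """Map centimorgans back to a recombination fraction, t = tanh(d/50)/2."""
    if cm < 0:
        raise ValueError(f"map distance must be >= 0, got {cm}")
    return 0.5 * math.tanh(cm / 50.0)


# ---------------------------------------------------------------------------
# meiosis panel


@dataclass
class Transmission:
    """One parent -> offspring gamete with per-marker inheritance records.

    ``alleles`` holds the transmitted allele at every marker where the parent
    is heterozygous and transmission is resolvable.  ``anchors`` is a
    deterministic 0/1 relabelling of the transmitted allele against the
    parent's sorted genotype (used by the phase-mixture likelihood), and
    ``origins`` holds the grandparental origin (0 = grandpaternal,
    1 = grandmaternal) at the subset of markers where the parent's phase is
    resolved.
    """

    parent: str
    parent_sex: str
    offspring: str
    population: str = "pop"
    alleles: dict = field(default_factory=dict)
    anchors: dict = field(default_factory=dict)
    origins: dict = field(default_factory=dict)


_SEX_CODE = {FEMALE: 0, MALE: 1, UNKNOWN: 2}


class MeiosisPanel:
    """Phased inheritance observations for a marker panel."""

    def __init__(self, markers: Sequence[str],
                 transmissions: Iterable[Transmission]):
        self.markers = list(markers)
        self.transmissions = [t for t in transmissions if t.alleles]
        self._midx = {m: i for i, m in enumerate(self.markers)}
        self._compiled = None

    def subset_population(self, population: str) -> "MeiosisPanel":
        return MeiosisPanel(self.markers,
                            [t for t in self.transmissions
                             if t.population == population])

    # -- compiled numeric view -------------------------------------------
    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        n, m = len(self.transmissions), len(self.markers)
        anc = np.full((n, m), -1, dtype=np.int8)
        org = np.full((n, m), -1, dtype=np.int8)
        parents = sorted({t.parent for t in self.transmissions})
        pidx = {p: i for i, p in enumerate(parents)}
        par = np.zeros(n, dtype=np.int64)
        sex = np.zeros(n, dtype=np.int8)
        for r, t in enumerate(self.transmissions):
            par[r] = pidx[t.parent]
            sex[r] = _SEX_CODE.get(t.parent_sex, 2)
            for mk, a in t.anchors.items():
                anc[r, self._midx[mk]] = a
            for mk, o in t.origins.items():
                org[r, self._midx[mk]] = o
        self._compiled = (anc, org, par, sex, len(parents))
        return self._compiled

    def n_informative(self, marker: str, sex: str | None = None) -> int:
        j = self._midx[marker]
        anc, _org, _par, sexes, _np_ = self._compile()
        mask = anc[:, j] >= 0
        if sex is not None:
            mask &= sexes == _SEX_CODE[sex]
        return int(mask.sum())


def phase_meioses(pedigree: Pedigree, genotypes: GenotypeTable) -> MeiosisPanel:
    """Resolve transmitted alleles and grandparental origins for every
    parent -> offspring transmission in the pedigree.

    Run :func:`ovismap.pedigree.mendelian_check` first: inconsistent
    genotypes produce unresolvable (silently dropped) or misleading records.
    """
    # per (parent, marker): phase map allele -> origin, resolved via the
    # parent's own parents
    phase_cache: dict[tuple[str, str], dict | None] = {}

    def parent_phase(parent_id: str, marker: str):
        key = (parent_id, marker)
        if key in phase_cache:
            return phase_cache[key]
        res = None
        par = pedigree.individuals[parent_id]
        pgt = genotypes.get(parent_id, marker)
        if pgt is not None and pgt[0] != pgt[1]:
            gs = genotypes.get(par.sire_id, marker) if par.sire_id else None
            gd = genotypes.get(par.dam_id, marker) if par.dam_id else None
            if gs is not None:
                from_sire = transmitted_allele(gs, gd, pgt)
                if from_sire is not None:
                    other = pgt[0] if pgt[1] == from_sire else pgt[1]
                    res = {from_sire: 0, other: 1}
            if res is None and gd is not None:
                from_dam = transmitted_allele(gd, gs, pgt)
                if from_dam is not None:
                    other = pgt[0] if pgt[1] == from_dam else pgt[1]
                    res = {other: 0, from_dam: 1}
        phase_cache[key] = res
        return res

    out: list[Transmission] = []
    for parent_id, parent_sex, other_id, off_id in _transmissions(pedigree):
        if parent_id not in pedigree:
            continue
        pop = pedigree.individuals[off_id].population
        t = Transmission(parent_id, parent_sex, off_id, pop)
        for marker in genotypes.markers:
            pgt = genotypes.get(parent_id, marker)
            if pgt is None or pgt[0] == pgt[1]:
                continue
            off = genotypes.get(off_id, marker)
            if off is None:
                continue
            other = genotypes.get(other_id, marker) if other_id else None
            allele = transmitted_allele(pgt, other, off)
            if allele is None:
                continue
            t.alleles[marker] = allele
            t.anchors[marker] = 0 if allele == pgt[0] else 1
            ph = parent_phase(parent_id, marker)
            if ph is not None:
                t.origins[marker] = ph[allele]
        if t.alleles:
            out.append(t)
    return MeiosisPanel(genotypes.markers, out)


# ---------------------------------------------------------------------------
# pairwise / flank-pair likelihood machinery


@dataclass
class PairStats:
    """Sufficient statistics for one marker (flank) pair.

    ``R`` of ``N`` phase-known meioses are recombinant; ``mix_r[i]`` of
    ``mix_n[i]`` anchor-recombinant among the i-th phase-uncertain parent's
    offspring (anchor relabelling is phase-symmetric, hence the mixture).
    """

    R: int = 0
    N: int = 0
    mix_r: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    mix_n: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def n_meioses(self) -> int:
        return int(self.N + self.mix_n.sum())

    def log10_lik(self, theta: float) -> float:
        th = min(max(theta, 1e-12), 0.5)
        s = 0.0
        if self.N:
            s += self.R * math.log10(th) if self.R else 0.0
            s += (self.N - self.R) * math.log10(1.0 - th) if self.N - self.R else 0.0
        if self.mix_n.size:
            lt, l1 = math.log(th), math.log1p(-th)
            a = self.mix_r * lt + (self.mix_n - self.mix_r) * l1
            b = (self.mix_n - self.mix_r) * lt + self.mix_r * l1
            hi = np.maximum(a, b)
            s += float((math.log(0.5) + hi
                        + np.log1p(np.exp(np.minimum(a, b) - hi))).sum()) / LOG10
        return s

    def log10_lik_null(self) -> float:
        """log10 L at theta = 0.5 (free recombination)."""
        return -float(self.N + self.mix_n.sum()) * math.log10(2.0)


def _golden_max(f, lo: float, hi: float, tol: float = THETA_TOL) -> float:
    """Golden-section maximiser of a unimodal scalar function on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def mle_theta(stats: PairStats) -> tuple[float, float]:
    """(theta_hat, profile log10 L) on [0, 0.5].

    Closed form R/N when the pair is purely phase-known; otherwise a coarse
    grid bracket followed by golden-section refinement to ``THETA_TOL``.
    """
    if stats.n_meioses == 0:
        return math.nan, 0.0
    if stats.mix_n.size == 0:
        th = min(stats.R / stats.N, 0.5)
        return th, stats.log10_lik(th)
    grid = np.linspace(1e-9, 0.5, 41)
    vals = [stats.log10_lik(t) for t in grid]
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    th = _golden_max(stats.log10_lik, lo, hi)
    # endpoints can beat an interior bracket when the optimum is at a bound
    cands = [th, 0.0, 0.5]
    vals2 = [stats.log10_lik(max(t, 1e-12)) for t in cands]
    j = int(np.argmax(vals2))
    return cands[j], vals2[j]


@dataclass
class TwoPointResult:
    marker1: str
    marker2: str
    theta: float
    theta_f: float
    theta_m: float
    lod: float
    n_meioses: int
    n_meioses_f: int
    n_meioses_m: int
    R: int  # phase-known recombinants (pooled)
    N: int  # phase-known meioses (pooled)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.marker1, self.marker2))


class MultipointEvaluator:
    """Fast flank-pair accumulator + cached profile likelihoods for orders
    over a fixed marker subset of one panel."""

    def __init__(self, panel: MeiosisPanel, markers: Sequence[str] | None = None):
        self.panel = panel
        self.markers = list(markers) if markers is not None else list(panel.markers)
        anc, org, par, sex, n_par = panel._compile()
        cols = np.array([panel._midx[m] for m in self.markers], dtype=np.int64)
        if cols.size:
            self._anc = anc[:, cols]
            self._org = org[:, cols]
        else:  # pragma: no cover - degenerate
            self._anc = anc[:, :0]
            self._org = org[:, :0]
        keep = (self._anc >= 0).any(axis=1)
        self._anc = np.ascontiguousarray(self._anc[keep])
        self._org = np.ascontiguousarray(self._org[keep])
        self._par = par[keep]
        self._sex = sex[keep]
        self._n_par = n_par
        self._lidx = {m: i for i, m in enumerate(self.markers)}
        self._cache: dict = {}

    # -- accumulation -----------------------------------------------------
    def pair_stats(self, order: Sequence[str],
                   sex: str | None = None) -> dict[tuple[int, int], PairStats]:
        """Sufficient statistics per flank pair, keyed by (i, j) positions in
        ``order`` (i < j; markers between i and j were uninformative in every
        contributing meiosis)."""
        cols = np.array([self._lidx[m] for m in order], dtype=np.int64)
        anc = self._anc[:, cols]
        org = self._org[:, cols]
        par = self._par
        if sex is not None:
            rows = self._sex == _SEX_CODE[sex]
            anc, org, par = anc[rows], org[rows], par[rows]
        k = len(cols)
        if k < 2 or anc.shape[0] == 0:
            return {}
        inf = anc >= 0
        colidx = np.broadcast_to(np.arange(k, dtype=np.int64), anc.shape)
        pos = np.where(inf, colidx, -1)
        cummax = np.maximum.accumulate(pos, axis=1)
        prev = np.full(anc.shape, -1, dtype=np.int64)
        prev[:, 1:] = cummax[:, :-1]
        valid = inf & (prev >= 0)
        r_i, c_i = np.nonzero(valid)
        if r_i.size == 0:
            return {}
        pc = prev[r_i, c_i]
        pairid = pc * k + c_i
        o_hi = org[r_i, c_i]
        o_lo = org[r_i, pc]
        known = (o_hi >= 0) & (o_lo >= 0)
        sw_org = (o_hi != o_lo) & known
        sw_anc = anc[r_i, c_i] != anc[r_i, pc]

        stats: dict[int, PairStats] = {}
        if known.any():
            kp = pairid[known]
            n_k = np.bincount(kp, minlength=k * k)
            r_k = np.bincount(kp[sw_org[known]], minlength=k * k)
            for pid in np.nonzero(n_k)[0]:
                stats[int(pid)] = PairStats(R=int(r_k[pid]), N=int(n_k[pid]))
        unk = ~known
        if unk.any():
            # dense (pair, parent) key space; parents sorted within pair so
            # per-pair slices are contiguous after flatnonzero
            key = pairid[unk] * self._n_par + par[r_i[unk]]
            size = k * k * self._n_par
            n_cnt = np.bincount(key, minlength=size)
            r_cnt = np.bincount(key[sw_anc[unk]], minlength=size)
            nz = np.flatnonzero(n_cnt)
            pair_of = nz // self._n_par
            bounds = np.flatnonzero(np.diff(pair_of)) + 1
            for pid_arr, r_arr, n_arr in zip(np.split(pair_of, bounds),
                                             np.split(r_cnt[nz], bounds),
                                             np.split(n_cnt[nz], bounds)):
                st = stats.setdefault(int(pid_arr[0]), PairStats())
                st.mix_r = r_arr.astype(np.int64)
                st.mix_n = n_arr.astype(np.int64)
        return {(int(pid // k), int(pid % k)): st for pid, st in stats.items()}

    # -- likelihood -------------------------------------------------------
    def _pair_profile(self, order: Sequence[str], ij: tuple[int, int],
                      st: PairStats) -> float:
        i, j = ij
        a, b = order[i], order[j]
        if b < a:
            a, b = b, a
        key = (a, b, frozenset(order[i + 1:j]))
        val = self._cache.get(key)
        if val is None:
            val = mle_theta(st)[1]
            self._cache[key] = val
        return val

    def loglik(self, order: Sequence[str]) -> float:
        """Profile multipoint log10-likelihood of an order.

        Absolute (no theta = 0.5 baseline subtracted): for two markers it
        equals the two-point profile log10 L(theta_hat), i.e. the two-point
        LOD plus log10 L(0.5).  Invariant under whole-order reversal.
        """
        ps = self.pair_stats(order)
        return sum(self._pair_profile(order, ij, st) for ij, st in ps.items())


def multipoint_loglik(order: Sequence[str], panel: MeiosisPanel) -> float:
    """Convenience wrapper; see :meth:`MultipointEvaluator.loglik`."""
    if len(order) < 2:
        raise ValueError("order must cover at least 2 markers")
    return MultipointEvaluator(panel, list(order)).loglik(list(order))


def twopoint(panel: MeiosisPanel, m1: str, m2: str,
             _ev: MultipointEvaluator | None = None) -> TwoPointResult | None:
    """Two-point MLE of theta and LOD for one marker pair; sex-specific
    estimates maximise the same likelihood restricted to meioses of each
    parent sex.  Returns ``None`` when the pair shares no informative
    meioses."""
    ev = _ev if _ev is not None else MultipointEvaluator(panel, [m1, m2])
    order = [m1, m2]
    pooled = ev.pair_stats(order).get((0, 1))
    if pooled is None or pooled.n_meioses == 0:
        return None
    th, ll = mle_theta(pooled)
    lod = ll - pooled.log10_lik_null()
    fem = ev.pair_stats(order, sex=FEMALE).get((0, 1))
    mal = ev.pair_stats(order, sex=MALE).get((0, 1))
    th_f = mle_theta(fem)[0] if fem is not None else math.nan
    th_m = mle_theta(mal)[0] if mal is not None else math.nan
    return TwoPointResult(
        marker1=m1, marker2=m2, theta=th, theta_f=th_f, theta_m=th_m,
        lod=max(lod, 0.0), n_meioses=pooled.n_meioses,
        n_meioses_f=fem.n_meioses if fem else 0,
        n_meioses_m=mal.n_meioses if mal else 0,
        R=pooled.R, N=pooled.N)


def twopoint_all(panel: MeiosisPanel,
                 markers: Sequence[str] | None = None) -> list[TwoPointResult]:
    """Two-point results for every marker pair with shared informative
    meioses (pairs without any are skipped)."""
    markers = list(markers) if markers is not None else list(panel.markers)
    out = []
    for m1, m2 in combinations(markers, 2):
        ev = MultipointEvaluator(panel, [m1, m2])
        res = twopoint(panel, m1, m2, _ev=ev)
        if res is not None:
            out.append(res)
    return out


# ---------------------------------------------------------------------------
# grouping


def form_linkage_groups(results: Iterable[TwoPointResult],
                        markers: Sequence[str],
                        lod_threshold: float = 4.0) -> list[set[str]]:
    """Connected components of the marker graph with edges at LOD >
    ``lod_threshold``.  Markers without a qualifying edge become singleton
    groups."""
    g = nx.Graph()
    g.add_nodes_from(markers)
    for r in results:
        if r.lod > lod_threshold:
            g.add_edge(r.marker1, r.marker2)
    return sorted((set(c) for c in nx.connected_components(g)),
                  key=lambda s: (-len(s), min(s)))


def _ref_neighbors(marker: str, reference_map: dict,
                   universe: set[str]) -> set[str]:
    """Markers adjacent to ``marker`` on its reference chromosome, among the
    reference markers present in this analysis."""
    if marker not in reference_map:
        return set()
    chrom, _pos = reference_map[marker]
    on_chrom = sorted((m for m in universe
                       if m in reference_map and reference_map[m][0] == chrom),
                      key=lambda m: (reference_map[m][1], m))
    try:
        i = on_chrom.index(marker)
    except ValueError:
        return set()
    out = set()
    if i > 0:
        out.add(on_chrom[i - 1])
    if i + 1 < len(on_chrom):
        out.add(on_chrom[i + 1])
    return out


def curate_synteny(partition: list[set[str]],
                   results: Iterable[TwoPointResult],
                   reference_map: dict | None,
                   lod_threshold: float = 4.0
                   ) -> tuple[list[set[str]], list[str]]:
    """Cut weakly supported cross-chromosome bridges inside linkage groups.

    Two-point LOD scores between truly unlinked markers are overdispersed
    relative to their nominal binomial sampling error (phase resolution is a
    selected subset of transmissions), so single-linkage grouping
    occasionally welds two chromosomes together through one marginal edge.
    Mirroring how reference-map synteny conflicts are curated by hand in
    practice, an edge between markers on different reference chromosomes is
    removed when, for both endpoints, some same-reference-chromosome partner
    shows stronger linkage; components are then recomputed.  Markers whose
    strongest linkage genuinely lies on another chromosome (a real
    rearrangement) keep their edges.
    """
    log: list[str] = []
    if reference_map is None:
        return [set(g) for g in partition], log
    results = list(results)
    best_same: dict[str, float] = {}
    for r in results:
        ca = reference_map.get(r.marker1, (None,))[0]
        cb = reference_map.get(r.marker2, (None,))[0]
        if ca is not None and ca == cb:
            for m in (r.marker1, r.marker2):
                best_same[m] = max(best_same.get(m, -math.inf), r.lod)
    out: list[set[str]] = []
    for group in partition:
        g = nx.Graph()
        g.add_nodes_from(group)
        for r in results:
            if r.lod > lod_threshold and r.marker1 in group and r.marker2 in group:
                g.add_edge(r.marker1, r.marker2, lod=r.lod)
        for a, b, data in list(g.edges(data=True)):
            ca = reference_map.get(a, (None,))[0]
            cb = reference_map.get(b, (None,))[0]
            if ca is None or cb is None or ca == cb:
                continue
            if (data["lod"] < best_same.get(a, -math.inf)
                    and data["lod"] < best_same.get(b, -math.inf)):
                g.remove_edge(a, b)
                log.append(f"cut {a}({ca})-{b}({cb}) bridge "
                           f"(LOD {data['lod']:.2f}, both markers link "
                           f"more strongly within their own chromosome)")
        out.extend(set(c) for c in nx.connected_components(g))
    return sorted(out, key=lambda s: (-len(s), min(s))), log


def assign_stragglers(partition: list[set[str]],
                      results: Iterable[TwoPointResult],
                      reference_map: dict | None
                      ) -> tuple[list[set[str]], list[str]]:
    """Reference-map rescue of unassigned markers and fragmented groups.

    A singleton joins the group of its overall highest-LOD partner when that
    partner is its immediate neighbour on the reference map.  Two groups
    whose markers sit on the same reference chromosome are merged when the
    best LOD between their reference end markers is, for both end markers,
    their best LOD outside their own group.  Every action is logged with its
    evidence; without a reference map the partition is returned unchanged.
    """
    log: list[str] = []
    if reference_map is None:
        return [set(g) for g in partition], log
    lod: dict[frozenset, float] = {}
    best_partner: dict[str, tuple[float, str]] = {}
    for r in results:
        lod[r.pair] = max(lod.get(r.pair, -math.inf), r.lod)
        for a, b in ((r.marker1, r.marker2), (r.marker2, r.marker1)):
            cur = best_partner.get(a)
            if cur is None or (r.lod, b) > cur:
                best_partner[a] = (r.lod, b)
    groups = [set(g) for g in partition]
    universe = set().union(*groups) if groups else set()

    # rule 1: singleton rescue via reference adjacency
    for g in list(groups):
        if len(g) != 1:
            continue
        (m,) = g
        bp = best_partner.get(m)
        if bp is None:
            continue
        score, partner = bp
        if partner in _ref_neighbors(m, reference_map, universe):
            target = next(h for h in groups if partner in h)
            if target is not g:
                target.add(m)
                groups.remove(g)
                log.append(f"assigned {m} to group of {partner} "
                           f"(top LOD {score:.2f}, reference neighbour)")

    # rule 2: merge same-chromosome groups on mutual-best end-marker LOD
    def group_chrom(g: set[str]) -> str | None:
        chroms = [reference_map[m][0] for m in g if m in reference_map]
        if not chroms:
            return None
        return max(sorted(set(chroms)), key=chroms.count)

    def end_markers(g: set[str]) -> list[str]:
        refd = sorted((m for m in g if m in reference_map),
                      key=lambda m: (reference_map[m][1], m))
        if not refd:
            return sorted(g)[:1]
        return list({refd[0], refd[-1]})

    merged = True
    while merged:
        merged = False
        for g1, g2 in combinations(list(groups), 2):
            c1, c2 = group_chrom(g1), group_chrom(g2)
            if c1 is None or c1 != c2:
                continue
            pairs = [(a, b) for a in end_markers(g1) for b in end_markers(g2)
                     if frozenset((a, b)) in lod]
            if not pairs:
                continue
            a, b = max(pairs, key=lambda p: (lod[frozenset(p)], p))
            score = lod[frozenset((a, b))]

            def rank_outside(m: str, own: set[str]) -> int:
                """1-based rank of ``score`` among m's LODs to markers
                outside its own group (1 = highest)."""
                vals = sorted((v for pr, v in lod.items()
                               if m in pr and not (pr - {m}) <= own),
                              reverse=True)
                return 1 + sum(1 for v in vals if v > score)

            # linkage assumed when the end-marker LOD ranks highest for both
            # end markers (outside their own groups)
            if rank_outside(a, g1) == 1 and rank_outside(b, g2) == 1:
                g1.update(g2)
                groups.remove(g2)
                log.append(f"merged groups on reference chromosome {c1} via "
                           f"end markers {a}-{b} (LOD {score:.2f})")
                merged = True
                break
    return sorted(groups, key=lambda s: (-len(s), min(s))), log


# ---------------------------------------------------------------------------
# ordering


def orient_order(order: Sequence[str],
                 reference_map: dict | None = None) -> list[str]:
    """Canonical orientation: the shared marker with the smallest reference
    position goes in the lower half; without a reference, lexicographic
    (first marker <= last marker)."""
    order = list(order)
    if len(order) < 2:
        return order
    if reference_map:
        shared = [m for m in order if m in reference_map]
        if shared:
            first = min(shared, key=lambda m: (reference_map[m][1], m))
            i = order.index(first)
            if i > len(order) - 1 - i:
                order.reverse()
            return order
    if order[-1] < order[0]:
        order.reverse()
    return order


def order_build(group: Iterable[str], panel: MeiosisPanel,
                lod_ladder: Sequence[float] = (3.0, 2.0, 1.0, 0.5, 0.0),
                min_seed_meioses: int = 20,
                evaluator: MultipointEvaluator | None = None
                ) -> tuple[list[str], MultipointEvaluator]:
    """Greedy marker insertion under a descending LOD ladder.

    Seeds with the highest-LOD pair among pairs with at least
    ``min_seed_meioses`` jointly informative meioses (ties broken
    lexicographically), then repeatedly inserts the remaining marker whose
    best insertion position beats its second-best by at least the current
    ladder value (largest margin first).  At ladder value 0 every marker is
    placed at its best position, so the returned order is always complete.
    """
    markers = sorted(group)
    ev = evaluator or MultipointEvaluator(panel, markers)
    if len(markers) < 2:
        return markers, ev
    # seed pair
    best_seed = None
    for m1, m2 in combinations(markers, 2):
        st = ev.pair_stats([m1, m2]).get((0, 1))
        if st is None or st.n_meioses == 0:
            continue
        th, ll = mle_theta(st)
        lodv = ll - st.log10_lik_null()
        qualifies = st.n_meioses >= min_seed_meioses
        key = (qualifies, lodv, st.n_meioses, (m1, m2))
        if best_seed is None or key > best_seed[0]:
            best_seed = (key, [m1, m2])
    if best_seed is None:
        return markers, ev  # no jointly informative pair at all
    order = best_seed[1]
    remaining = [m for m in markers if m not in order]
    for threshold in lod_ladder:
        progress = True
        while progress and remaining:
            progress = False
            candidates = []
            for m in remaining:
                lls = [(ev.loglik(order[:i] + [m] + order[i:]), -i)
                       for i in range(len(order) + 1)]
                lls.sort(reverse=True)
                margin = lls[0][0] - lls[1][0]
                candidates.append((margin, m, -lls[0][1]))
            candidates.sort(key=lambda c: (-c[0], c[1]))
            margin, m, pos = candidates[0]
            if margin >= threshold - 1e-12:
                order.insert(pos, m)
                remaining.remove(m)
                progress = True
    return order, ev


def refine_flips(order: Sequence[str], panel: MeiosisPanel, window: int = 5,
                 evaluator: MultipointEvaluator | None = None
                 ) -> tuple[list[str], float]:
    """Exhaustive permutation of every sliding window of adjacent loci.

    Adopts the best strictly improving order and iterates to a fixed point.
    Returns the refined order and the final order's log10-likelihood margin
    over the best rejected alternative of the last sweep (>= 0; a margin of
    0 means an equally likely alternative exists, e.g. the whole-order
    reversal when ``window`` spans the group).
    """
    cur = list(order)
    ev = evaluator or MultipointEvaluator(panel, cur)
    if len(cur) < 2:
        return cur, math.inf
    w = min(window, len(cur))
    cur_ll = ev.loglik(cur)
    margin = math.inf
    improved = True
    while improved:
        improved = False
        best_alt = -math.inf
        best_cand = None
        for start in range(len(cur) - w + 1):
            segment = tuple(cur[start:start + w])
            for perm in permutations(segment):
                if perm == segment:
                    continue
                cand = cur[:start] + list(perm) + cur[start + w:]
                ll = ev.loglik(cand)
                if ll > best_alt:
                    best_alt = ll
                    best_cand = cand
        if best_cand is not None and best_alt > cur_ll + 1e-9:
            cur, cur_ll = best_cand, best_alt
            improved = True
        else:
            margin = cur_ll - best_alt if best_cand is not None else math.inf
    return cur, margin


# ---------------------------------------------------------------------------
# double-recombinant screening


@dataclass
class DoubleRecombinantFlag:
    parent: str
    offspring: str
    marker: str
    flank_span_cm: float


def flag_double_recombinants(order: Sequence[str], panel: MeiosisPanel,
                             positions: dict[str, float],
                             span_cm_limit: float = 20.0
                             ) -> list[DoubleRecombinantFlag]:
    """Flag isolated grandparental-origin states whose two flanking switches
    lie within ``span_cm_limit`` (exclusive) on the current map.

    Only phase-known origin strings are screened.  Flags identify the
    genotype most likely to be erroneous; masking is left to the caller
    (see :func:`mask_flagged`).
    """
    flags: list[DoubleRecombinantFlag] = []
    if span_cm_limit <= 0:
        return flags
    pos_in_order = {m: i for i, m in enumerate(order)}
    for t in panel.transmissions:
        obs = sorted(((pos_in_order[m], m) for m in t.origins
                      if m in pos_in_order))
        for k in range(1, len(obs) - 1):
            _, m_prev = obs[k - 1]
            _, m_here = obs[k]
            _, m_next = obs[k + 1]
            o_prev, o_here, o_next = (t.origins[m_prev], t.origins[m_here],
                                      t.origins[m_next])
            if o_here != o_prev and o_here != o_next:
                span = abs(positions[m_next] - positions[m_prev])
                if span < span_cm_limit:
                    flags.append(DoubleRecombinantFlag(
                        t.parent, t.offspring, m_here, span))
    return flags


def mask_flagged(genotypes: GenotypeTable,
                 flags: Iterable[DoubleRecombinantFlag]) -> GenotypeTable:
    """Set the offspring genotype missing at every flagged marker."""
    table = genotypes.copy()
    for f in flags:
        table.set(f.offspring, f.marker, None)
    return table


# ---------------------------------------------------------------------------
# map estimation


@dataclass
class Interval:
    """One adjacent-marker interval of an estimated map.

    ``theta``/``cm`` triplets are (sex-averaged, female, male); a value is
    ``None`` when no informative meiosis of that class spans the interval or
    the theta estimate is at the unlinked boundary (0.5)."""

    left: str
    right: str
    theta_avg: float | None
    theta_f: float | None
    theta_m: float | None
    cm_avg: float | None
    cm_f: float | None
    cm_m: float | None
    n_avg: int
    n_f: int
    n_m: int


@dataclass
class LinkageGroup:
    name: str
    markers: list[str]
    intervals: list[Interval]
    log10_likelihood: float | None = None

    def length(self, which: str = "avg") -> float:
        """Summed interval length in cM; undefined intervals are excluded."""
        return sum(cm for iv in self.intervals
                   if (cm := getattr(iv, f"cm_{which}")) is not None)

    def positions(self, which: str = "avg") -> dict[str, float]:
        """Cumulative cM positions from the first marker (undefined interval
        lengths advance the cursor by 0)."""
        pos = {self.markers[0]: 0.0}
        cur = 0.0
        for iv in self.intervals:
            cm = getattr(iv, f"cm_{which}")
            cur += cm if cm is not None else 0.0
            pos[iv.right] = cur
        return pos

    def co_located_sets(self) -> list[list[str]]:
        """Runs of markers at a single map position (theta = 0 links)."""
        runs, run = [], [self.markers[0]]
        for iv in self.intervals:
            if iv.theta_avg is not None and iv.theta_avg <= 1e-9:
                run.append(iv.right)
            else:
                if len(run) > 1:
                    runs.append(run)
                run = [iv.right]
        if len(run) > 1:
            runs.append(run)
        return runs

    @property
    def n_unique_positions(self) -> int:
        dup = sum(len(r) - 1 for r in self.co_located_sets())
        return len(self.markers) - dup


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    @property
    def n_intervals(self) -> int:
        return sum(len(g.intervals) for g in self.groups)

    def total_length(self, which: str = "avg") -> float:
        return sum(g.length(which) for g in self.groups)

    @property
    def n_unique_positions(self) -> int:
        return sum(g.n_unique_positions for g in self.groups)


def _interval_theta(stats: PairStats | None) -> tuple[float | None, float | None, int]:
    if stats is None or stats.n_meioses == 0:
        return None, None, 0
    th, _ll = mle_theta(stats)
    if th >= THETA_UNLINKED:
        return th, None, stats.n_meioses
    return th, kosambi(th), stats.n_meioses


def estimate_map(order: Sequence[str], panel: MeiosisPanel,
                 name: str = "LG",
                 evaluator: MultipointEvaluator | None = None) -> LinkageGroup:
    """Per-interval recombination fractions for a fixed order.

    Each interval's theta is estimated from the meioses whose nearest
    informative flanks are exactly that interval's two markers: pooled over
    sexes (sex-averaged MLE, not a mean of the sex-specific estimates), then
    maternal-only and paternal-only.  cM lengths via the Kosambi function.
    """
    order = list(order)
    ev = evaluator or MultipointEvaluator(panel, order)
    by_sex = {"avg": ev.pair_stats(order),
              "f": ev.pair_stats(order, sex=FEMALE),
              "m": ev.pair_stats(order, sex=MALE)}
    intervals = []
    for i in range(len(order) - 1):
        key = (i, i + 1)
        th_a, cm_a, n_a = _interval_theta(by_sex["avg"].get(key))
        th_f, cm_f, n_f = _interval_theta(by_sex["f"].get(key))
        th_m, cm_m, n_m = _interval_theta(by_sex["m"].get(key))
        intervals.append(Interval(order[i], order[i + 1],
                                  th_a, th_f, th_m, cm_a, cm_f, cm_m,
                                  n_a, n_f, n_m))
    ll = ev.loglik(order) if len(order) >= 2 else None
    return LinkageGroup(name=name, markers=order, intervals=intervals,
                        log10_likelihood=ll)


def split_long_intervals(lmap: LinkageMap, limit: float = 50.0,
                         keep_together: Iterable[frozenset] | None = None
                         ) -> tuple[LinkageMap, list[str]]:
    """Break groups at sex-averaged intervals longer than ``limit`` cM.

    Intervals with an undefined sex-averaged length (no linkage) also split.
    ``keep_together`` marker pairs override the rule (logged), mirroring the
    judgement call of keeping a group intact when one sex shows tight
    linkage across the gap.
    """
    keep = {frozenset(p) for p in keep_together} if keep_together else set()
    log: list[str] = []
    groups: list[LinkageGroup] = []
    for g in lmap.groups:
        part_markers: list[list[str]] = [[g.markers[0]]] if g.markers else [[]]
        part_intervals: list[list[Interval]] = [[]]
        for iv in g.intervals:
            too_long = iv.cm_avg is None or iv.cm_avg > limit
            what = "undefined" if iv.cm_avg is None else f"{iv.cm_avg:.1f} cM"
            if too_long and frozenset((iv.left, iv.right)) in keep:
                log.append(f"{g.name}: kept {iv.left}-{iv.right} ({what}) by override")
                too_long = False
            if too_long:
                log.append(f"{g.name}: split at {iv.left}-{iv.right} ({what})")
                part_markers.append([iv.right])
                part_intervals.append([])
            else:
                part_markers[-1].append(iv.right)
                part_intervals[-1].append(iv)
        if len(part_markers) == 1:
            groups.append(g)
            continue
        suffixes = iter("abcdefghijklmnopqrstuvwxyz")
        for markers, ivs in zip(part_markers, part_intervals):
            groups.append(LinkageGroup(name=f"{g.name}{next(suffixes)}",
                                       markers=markers, intervals=ivs,
                                       log10_likelihood=None))
    return LinkageMap(groups=groups), log
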