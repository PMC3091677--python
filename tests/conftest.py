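"""Shared fixtures: tiny hand-built pedigrees and small simulated studies."""

from __future__ import annotations

import numpy as np
import pytest

from ovismap import (GenotypeTable, Individual, Pedigree, PopulationConfig,
                     SimulationConfig, phase_meioses, simulate_study)


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Sire + dam + one offspring."""
    return Pedigree([
        Individual("sire", None, None, "male"),
        Individual("dam", None, None, "female"),
        Individual("kid", "sire", "dam", "female"),
    ])


@pytest.fixture
def three_generation_pedigree() -> Pedigree:
    """Grandparents -> parents -> grandchildren; grandchildren transmissions
    are phase-resolvable wherever genotypes allow."""
    inds = [
        Individual("gs", None, None, "male"),
        Individual("gd", None, None, "female"),
        Individual("gs2", None, None, "male"),
        Individual("gd2", None, None, "female"),
        Individual("sire", "gs", "gd", "male"),
        Individual("dam", "gs2", "gd2", "female"),
    ]
    inds += [Individual(f"kid{i}", "sire", "dam", "male" if i % 2 else "female")
             for i in range(6)]
    return Pedigree(inds)


def small_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """One small population, 2 chromosomes x 5 markers — seconds to map."""
    defaults = dict(
        populations=(PopulationConfig("A", n_founders=40, n_generations=3,
                                      n_sires=16, sire_mean=4.0, sire_sd=2.0,
                                      dam_mean=3.0, dam_sd=1.5),),
        n_chromosomes=2, markers_per_chromosome=5,
        typing_success=1.0, error_rate=0.0, seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """Clean (no missingness, no errors) small simulated study."""
    return simulate_study(small_study_config(seed=7))


@pytest.fixture(scope="session")
def small_panel(small_study):
    return phase_meioses(small_study.pedigree, small_study.genotypes)


def manual_panel_pedigree(n_offspring: int, with_grandparents: bool,
                          alleles=("A", "B")):
    """A single nuclear family whose sire is heterozygous at every marker;
    marker genotypes are filled in by the caller."""
    inds = []
    if with_grandparents:
        inds += [Individual("gs", None, None, "male"),
                 Individual("gd", None, None, "female")]
        inds.append(Individual("sire", "gs", "gd", "male"))
    else:
        inds.append(Individual("sire", None, None, "male"))
    inds.append(Individual("dam", None, None, "female"))
    inds += [Individual(f"kid{i}", "sire", "dam", "female")
             for i in range(n_offspring)]
    return Pedigree(inds)


def build_phase_known_panel(origin_strings: list[str],
                            markers: list[str] | None = None):
    """A MeiosisPanel with fully phase-known meioses from origin strings.

    Each string gives one transmission's grandparental origins over the
    markers ('A'/'B' per position); recombinants between adjacent markers
    are exactly the A<->B switches.  Built through genotypes so the panel
    is produced by the real phasing code: the sire is C/D at every marker
    with C from his sire, the dam is E/E, so each offspring genotype
    uniquely reveals the transmitted allele, and grandparental genotypes
    resolve the sire's phase.
    """
    n_mark = max(len(s) for s in origin_strings)
    markers = markers or [f"M{j}" for j in range(n_mark)]
    inds = [Individual("gs", None, None, "male"),
            Individual("gd", None, None, "female"),
            Individual("sire", "gs", "gd", "male"),
            Individual("dam", None, None, "female")]
    inds += [Individual(f"kid{i}", "sire", "dam", "female")
             for i in range(len(origin_strings))]
    ped = Pedigree(inds)
    table = GenotypeTable(markers)
    for m in markers:
        table.set("gs", m, ("C", "C"))
        table.set("gd", m, ("D", "D"))
        table.set("sire", m, ("C", "D"))
        table.set("dam", m, ("E", "E"))
    for i, s in enumerate(origin_strings):
        for j, ch in enumerate(s):
            allele = "C" if ch == "A" else "D"
            table.set(f"kid{i}", markers[j], (allele, "E"))
    panel = phase_meioses(ped, table)
    return panel, ped, table
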