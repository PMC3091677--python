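"""File formats, run manifests and the end-to-end mapping pipeline.

Dialects (all tab-separated with headers):

* pedigree: ``id  sire  dam  sex  pop`` — missing parent ``0``, sex in
  {male, female, unknown} (or M/F/U);
* genotypes: ``id`` then two columns per marker (``MARKER.1``,
  ``MARKER.2``) — missing allele ``0``; half-missing calls are treated as
  missing;
* reference map: ``marker  chrom  pos_cM``;
* map table: one row per linkage group with marker/interval counts,
  sex-averaged/female/male lengths (0.1 cM) and interval-size bins
  [0,15), [15,30), [30,inf) cM, plus a Total row;
* interval table: one row per adjacent-marker interval with theta and cM
  estimates per sex class.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .mapping import (Interval, LinkageGroup, LinkageMap, MeiosisPanel,
                      MultipointEvaluator, assign_stragglers, curate_synteny,
                      estimate_map, flag_double_recombinants,
                      form_linkage_groups, mask_flagged, order_build,
                      orient_order, phase_meioses, refine_flips,
                      split_long_intervals, twopoint_all)
from .pedigree import (FEMALE, MALE, UNKNOWN, GenotypeTable, Individual,
                       Pedigree, delete_inconsistent, mendelian_check,
                       validate_pedigree)
from .simulate import PopulationConfig, SimulationConfig, simulate_study

__version__ = "0.1.0"

_SEX_CODES = {"male": MALE, "m": MALE, "female": FEMALE, "f": FEMALE,
              "unknown": UNKNOWN, "u": UNKNOWN, "0": UNKNOWN}

#: interval-size bin edges for map tables, cM (left-closed)
BIN_EDGES = (0.0, 15.0, 30.0)


class InputError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# readers


def read_pedigree(path) -> Pedigree:
    inds: list[Individual] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().split()
        if header[:4] != ["id", "sire", "dam", "sex"]:
            raise InputError(f"{path}:1: expected header 'id sire dam sex pop'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: expected >= 4 columns")
            iid, sire, dam, sex = parts[:4]
            pop = parts[4] if len(parts) > 4 else "pop"
            if iid in seen:
                raise InputError(f"{path}:{lineno}: duplicate individual id {iid!r}")
            seen.add(iid)
            if sex.lower() not in _SEX_CODES:
                raise InputError(f"{path}:{lineno}: unknown sex code {sex!r}")
            inds.append(Individual(iid,
                                   None if sire == "0" else sire,
                                   None if dam == "0" else dam,
                                   _SEX_CODES[sex.lower()], pop))
    return Pedigree(inds)


def read_genotypes(path) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "id":
            raise InputError(f"{path}:1: first column must be 'id'")
        allele_cols = header[1:]
        if len(allele_cols) % 2:
            raise InputError(f"{path}:1: odd number of allele columns")
        markers = []
        for i in range(0, len(allele_cols), 2):
            m1 = allele_cols[i].rsplit(".", 1)[0]
            m2 = allele_cols[i + 1].rsplit(".", 1)[0]
            if m1 != m2:
                raise InputError(f"{path}:1: allele columns {allele_cols[i]!r} "
                                 f"and {allele_cols[i + 1]!r} disagree")
            markers.append(m1)
        table = GenotypeTable(markers)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 1 + 2 * len(markers):
                raise InputError(f"{path}:{lineno}: expected "
                                 f"{1 + 2 * len(markers)} columns")
            iid = parts[0]
            for j, m in enumerate(markers):
                a, b = parts[1 + 2 * j], parts[2 + 2 * j]
                if a == "0" or b == "0":
                    continue
                table.set(iid, m, (_coerce(a), _coerce(b)))
    return table


def _coerce(allele: str):
    try:
        return int(allele)
    except ValueError:
        return allele


def read_reference_map(path) -> dict[str, tuple[str, float]]:
    out: dict[str, tuple[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["marker", "chrom", "pos_cM"]:
            raise InputError(f"{path}:1: expected header 'marker chrom pos_cM'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: expected 3 columns")
            if parts[0] in out:
                raise InputError(f"{path}:{lineno}: duplicate marker {parts[0]!r}")
            out[parts[0]] = (parts[1], float(parts[2]))
    return out


# ---------------------------------------------------------------------------
# writers


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\tsex\tpop\n")
        for ind in pedigree:
            fh.write(f"{ind.id}\t{ind.sire_id or 0}\t{ind.dam_id or 0}\t"
                     f"{ind.sex}\t{ind.population}\n")


def write_genotypes(genotypes: GenotypeTable, path,
                    individuals: Sequence[str] | None = None) -> None:
    inds = list(individuals) if individuals is not None else genotypes.individuals()
    with open(path, "w") as fh:
        cols = "\t".join(f"{m}.1\t{m}.2" for m in genotypes.markers)
        fh.write(f"id\t{cols}\n")
        for iid in inds:
            cells = []
            for m in genotypes.markers:
                gt = genotypes.get(iid, m)
                cells.append("0\t0" if gt is None else f"{gt[0]}\t{gt[1]}")
            fh.write(iid + "\t" + "\t".join(cells) + "\n")


def write_reference_map(reference: dict[str, tuple[str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tpos_cM\n")
        for m, (chrom, pos) in sorted(reference.items(),
                                      key=lambda kv: (kv[1][0], kv[1][1], kv[0])):
            fh.write(f"{m}\t{chrom}\t{pos:.4f}\n")


def write_true_map(true_map, path) -> None:
    """Simulator truth: ``marker chrom pos_f_cM pos_m_cM`` per marker."""
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tpos_f_cM\tpos_m_cM\n")
        for chrom in true_map.chromosomes:
            for m in true_map.markers[chrom]:
                fh.write(f"{m}\t{chrom}\t{true_map.pos_f[m]:.4f}\t"
                         f"{true_map.pos_m[m]:.4f}\n")


def write_truth(truth, path) -> None:
    """Simulator truth: grandparental origin of every transmitted allele."""
    with open(path, "w") as fh:
        fh.write("parent\toffspring\tmarker\torigin\n")
        for (parent, off), per_marker in sorted(truth.origins.items()):
            for m, o in per_marker.items():
                fh.write(f"{parent}\t{off}\t{m}\t{o}\n")


def write_map_table(lmap: LinkageMap, path) -> None:
    """Per-group summary in the style of a published map table.

    Interval-size bins count sex-averaged interval lengths in [0,15),
    [15,30) and [30,inf) cM (left-closed: a 15.0 cM interval falls in the
    middle bin); undefined intervals are not binned.
    """
    with open(path, "w") as fh:
        fh.write("group\tn_markers\tn_intervals\tsex_averaged_cM\tfemale_cM\t"
                 "male_cM\tbin_0_15\tbin_15_30\tbin_30_plus\n")
        tot = [0, 0, 0.0, 0.0, 0.0, 0, 0, 0]
        for g in lmap.groups:
            bins = [0, 0, 0]
            for iv in g.intervals:
                if iv.cm_avg is None:
                    continue
                if iv.cm_avg < BIN_EDGES[1]:
                    bins[0] += 1
                elif iv.cm_avg < BIN_EDGES[2]:
                    bins[1] += 1
                else:
                    bins[2] += 1
            row = [len(g.markers), len(g.intervals), g.length("avg"),
                   g.length("f"), g.length("m"), *bins]
            for i, v in enumerate(row):
                tot[i] += v
            fh.write(g.name + "\t" + "\t".join(
                f"{v:.1f}" if isinstance(v, float) else str(v)
                for v in row) + "\n")
        fh.write("Total\t" + "\t".join(
            f"{v:.1f}" if isinstance(v, float) else str(v)
            for v in tot) + "\n")


def read_map_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_interval_table(lmap: LinkageMap, path) -> None:
    cols = ("group\tleft\tright\ttheta_avg\ttheta_f\ttheta_m\t"
            "cm_avg\tcm_f\tcm_m\tn_avg\tn_f\tn_m\n")

    def fmt_theta(t: float | None) -> str:
        return "NA" if t is None else f"{t:.6f}"

    def fmt_cm(c: float | None) -> str:
        return "NA" if c is None else f"{c:.4f}"

    with open(path, "w") as fh:
        fh.write(cols)
        for g in lmap.groups:
            for iv in g.intervals:
                fh.write("\t".join([
                    g.name, iv.left, iv.right,
                    fmt_theta(iv.theta_avg), fmt_theta(iv.theta_f),
                    fmt_theta(iv.theta_m),
                    fmt_cm(iv.cm_avg), fmt_cm(iv.cm_f), fmt_cm(iv.cm_m),
                    str(iv.n_avg), str(iv.n_f), str(iv.n_m)]) + "\n")


def read_interval_table(path) -> LinkageMap:
    """Rebuild a LinkageMap (intervals + marker orders) from an interval
    table; group log-likelihoods are not stored and come back as ``None``."""
    df = pd.read_csv(path, sep="\t")

    def val(v):
        return None if pd.isna(v) else float(v)

    groups = []
    for name, sub in df.groupby("group", sort=False):
        intervals = [Interval(r.left, r.right,
                              val(r.theta_avg), val(r.theta_f), val(r.theta_m),
                              val(r.cm_avg), val(r.cm_f), val(r.cm_m),
                              int(r.n_avg), int(r.n_f), int(r.n_m))
                     for r in sub.itertuples()]
        markers = [intervals[0].left] + [iv.right for iv in intervals] \
            if intervals else []
        groups.append(LinkageGroup(str(name), markers, intervals))
    return LinkageMap(groups)


# ---------------------------------------------------------------------------
# manifest


@dataclass
class RunManifest:
    """Provenance record referenced by every pipeline output."""

    tool_version: str
    command: str
    seed: int | None
    config_hash: str
    input_digests: dict[str, str]
    parameters: dict
    started: str
    finished: str | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S%z")


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_PIPELINE = {
    "lod_threshold": 4.0,
    "lod_ladder": [3.0, 2.0, 1.0, 0.5, 0.0],
    "flips_window": 5,
    "split_limit_cm": 50.0,
    "double_recombinant_span_cm": 20.0,
    "mask_double_recombinants": False,
    "min_group_size": 2,
    "keep_together": [],
    "per_population": True,
}


@dataclass
class PipelineResult:
    maps: dict[str, LinkageMap]
    panel: MeiosisPanel
    mendelian_records: list
    straggler_log: list[str] = field(default_factory=list)
    split_log: list[str] = field(default_factory=list)
    flags: dict[str, list] = field(default_factory=dict)
    stage_log: list[str] = field(default_factory=list)
    manifest: RunManifest | None = None


def build_map(panel: MeiosisPanel, settings: dict | None = None,
              reference_map: dict | None = None,
              log: list[str] | None = None
              ) -> tuple[LinkageMap, list[str], list[str], list]:
    """Two-point -> group -> stragglers -> build -> flips -> double-recombinant
    screen -> fixed-order estimation -> long-interval split, for one panel."""
    cfg = {**DEFAULT_PIPELINE, **(settings or {})}
    log = log if log is not None else []
    results = twopoint_all(panel)
    log.append(f"twopoint: {len(results)} informative pairs over "
               f"{len(panel.markers)} markers")
    partition = form_linkage_groups(results, panel.markers,
                                    cfg["lod_threshold"])
    log.append(f"grouping: {len(partition)} groups at LOD > {cfg['lod_threshold']}")
    partition, cut_log = curate_synteny(partition, results, reference_map,
                                        cfg["lod_threshold"])
    partition, strag_log = assign_stragglers(partition, results, reference_map)
    strag_log = cut_log + strag_log
    groups = []
    flags_all = []
    for gi, group in enumerate(partition):
        if len(group) < cfg["min_group_size"]:
            continue
        order, ev = order_build(group, panel, tuple(cfg["lod_ladder"]))
        order, _margin = refine_flips(order, panel, cfg["flips_window"],
                                      evaluator=ev)
        order = orient_order(order, reference_map)
        lg = estimate_map(order, panel, name=f"LG{gi + 1}", evaluator=ev)
        span = cfg["double_recombinant_span_cm"]
        flags = flag_double_recombinants(order, panel, lg.positions("avg"),
                                         span)
        flags_all.extend(flags)
        log.append(f"{lg.name}: {len(order)} markers, "
                   f"{lg.length('avg'):.1f} cM sex-averaged, "
                   f"{len(flags)} double-recombinant flags")
        groups.append(lg)
    lmap = LinkageMap(groups)
    lmap, split_log = split_long_intervals(
        lmap, cfg["split_limit_cm"],
        [frozenset(p) for p in cfg["keep_together"]])
    return lmap, strag_log, split_log, flags_all


def run_pipeline(config: dict, out_dir=None, seed: int | None = None
                 ) -> PipelineResult:
    """Run the full study pipeline from a config mapping.

    The config either names input files (``pedigree``, ``genotypes`` and
    optionally ``reference_map``) or carries a ``simulate`` section; pipeline
    settings live under ``pipeline``.  Produces population-specific maps and
    an integrated map in which populations are treated as independent
    families (their likelihood contributions multiply).  Deterministic given
    config + seed.
    """
    started = _now()
    digests: dict[str, str] = {}
    stage_log: list[str] = []
    sim_section = config.get("simulate")
    if sim_section is not None:
        sim_cfg = simulation_config_from_dict(sim_section)
        if seed is not None:
            sim_cfg.seed = seed
        study = simulate_study(sim_cfg)
        pedigree, genotypes = study.pedigree, study.genotypes
        stage_log.append(f"simulate: {len(pedigree)} individuals, "
                         f"{len(genotypes.markers)} markers, seed {sim_cfg.seed}")
    else:
        for key in ("pedigree", "genotypes"):
            if key not in config:
                raise InputError(f"config missing required key {key!r}")
        pedigree = read_pedigree(config["pedigree"])
        genotypes = read_genotypes(config["genotypes"])
        digests["pedigree"] = _digest(config["pedigree"])
        digests["genotypes"] = _digest(config["genotypes"])
    reference = None
    if config.get("reference_map"):
        reference = read_reference_map(config["reference_map"])
        digests["reference_map"] = _digest(config["reference_map"])

    violations = validate_pedigree(pedigree)
    if violations:
        raise InputError("pedigree validation failed: "
                         + "; ".join(f"{v.individual}:{v.rule}" for v in violations[:5]))
    records = mendelian_check(pedigree, genotypes)
    clean = delete_inconsistent(genotypes, records)
    stage_log.append(f"mendelian: {len(records)} inconsistencies deleted")
    settings = {**DEFAULT_PIPELINE, **config.get("pipeline", {})}

    def analyse(panel: MeiosisPanel, label: str) -> tuple[LinkageMap, list, list, list]:
        lmap, strag, split, flags = build_map(panel, settings, reference,
                                              log=stage_log)
        if settings["mask_double_recombinants"] and flags:
            masked = mask_flagged(clean, flags)
            panel2 = phase_meioses(pedigree, masked)
            lmap, strag, split, flags = build_map(panel2, settings, reference,
                                                  log=stage_log)
            stage_log.append(f"{label}: re-estimated after masking "
                             f"{len(flags)} flagged genotypes")
        return lmap, strag, split, flags

    panel = phase_meioses(pedigree, clean)
    stage_log.append(f"phasing: {len(panel.transmissions)} transmissions")
    maps: dict[str, LinkageMap] = {}
    result = PipelineResult(maps=maps, panel=panel,
                            mendelian_records=records, stage_log=stage_log)
    pops = pedigree.populations()
    if settings["per_population"] and len(pops) > 1:
        for pop in pops:
            sub = panel.subset_population(pop)
            stage_log.append(f"population {pop}: "
                             f"{len(sub.transmissions)} transmissions")
            lmap, strag, split, flags = analyse(sub, pop)
            maps[pop] = lmap
            result.straggler_log.extend(f"{pop}: {s}" for s in strag)
            result.split_log.extend(f"{pop}: {s}" for s in split)
            result.flags[pop] = flags
    lmap, strag, split, flags = analyse(panel, "integrated")
    maps["integrated"] = lmap
    result.straggler_log.extend(f"integrated: {s}" for s in strag)
    result.split_log.extend(f"integrated: {s}" for s in split)
    result.flags["integrated"] = flags

    manifest = RunManifest(
        tool_version=__version__, command="map", seed=seed,
        config_hash=_config_hash(config), input_digests=digests,
        parameters=settings, started=started, finished=_now())
    result.manifest = manifest
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, m in maps.items():
            write_map_table(m, out / f"map_{label}.tsv")
            write_interval_table(m, out / f"intervals_{label}.tsv")
        with open(out / "stages.log", "w") as fh:
            fh.write("\n".join(stage_log + result.straggler_log
                               + result.split_log) + "\n")
        manifest.write(out / "manifest.json")
    return result


# ---------------------------------------------------------------------------
# config parsing


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    pops = d.pop("populations", None)
    cfg = SimulationConfig()
    if pops is not None:
        cfg.populations = tuple(PopulationConfig(**p) for p in pops)
    for key, value in d.items():
        if not hasattr(cfg, key):
            raise InputError(f"unknown simulation config key {key!r}")
        if key == "sdi_quadratic":
            value = tuple(value)
        setattr(cfg, key, value)
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a mapping")
    return cfg
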