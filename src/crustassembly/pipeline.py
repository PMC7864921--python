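"""End-to-end orchestration of the full analysis on one dataset.

``run_all`` reproduces the study shape on any conforming dataset directory:
ordination and group tests per study angle, regional distance-decay with
the line intersection, the environment Mantel screen, the five-process
assembly partition, the co-occurrence topology panel and the
sorting-environment correlations — separately for bacteria and eukaryota,
every stochastic stage seeded from one root seed.

Outputs are plain TSV/JSON with a fixed column order and a fixed float
format, so a rerun with the same manifest is byte-identical.  A stage
failure raises :class:`StageError` naming the stage; outputs written by
earlier stages are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly as asm
from . import beta_diversity as bd
from . import mediation as med
from . import network as net
from .core_io import (
    ANGLES,
    GroupAssignment,
    OtuTable,
    assign_groups,
    cumulative_abundance_filter,
    read_env_table,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    read_tree,
    to_relative,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

__all__ = ["RunConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    """All inputs, thresholds and seeds of one pipeline run."""

    input_dir: str
    out_dir: str
    seed: int
    angles: tuple[str, ...] = ANGLES
    n_perm: int = 999
    n_null: int = 999
    rho_threshold: float = 0.7
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    coverage: float = 0.99
    min_mean_rel: float = 1e-4
    decay_statistic: str = "R2"
    nmds_k: int = 2
    nmds_restarts: int = 4
    min_group_samples: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in (0, 1]")
        unknown = set(self.angles) - set(ANGLES)
        if unknown:
            raise ValueError(f"unknown angles: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "angles" in raw:
            raw["angles"] = tuple(raw["angles"])
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def _usable_angles(meta, angles, min_samples: int):
    """Angles with >= 2 levels of >= 2 samples on this dataset."""
    out = []
    for angle in angles:
        try:
            g = assign_groups(meta, angle)
        except ValueError as exc:
            logger.info("angle %s skipped: %s", angle, exc)
            continue
        sizes = [len(g.level_samples(l)) for l in g.levels]
        if sum(s >= 2 for s in sizes) >= 2:
            out.append(angle)
        else:
            logger.info("angle %s skipped: fewer than 2 usable levels", angle)
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run the complete analysis; returns a summary dict (also on disk).

    Stage order: load -> beta_diversity -> mediation -> assembly ->
    network -> sorting.  Later stages depend only on earlier outputs that
    exist in memory, so e.g. a missing tree aborts at the assembly stage
    with the ordination results already written.
    """
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    in_dir = Path(cfg.input_dir)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ("beta", "mediation", "assembly", "network", "decay"),
                 np.random.SeedSequence(cfg.seed).spawn(5))}
    summary: dict = {"stages": {}}

    # ---- load ------------------------------------------------------------
    try:
        otu = read_otu_table(in_dir / "otu.tsv")
        tax = read_taxonomy(in_dir / "taxonomy.tsv")
        meta = read_metadata(in_dir / "metadata.tsv")
        env = read_env_table(in_dir / "env.tsv")
        otu = OtuTable(otu.data.loc[meta.sample_ids], is_relative=otu.is_relative)
        domain_tables = {}
        for dom in ("Bacteria", "Eukaryota"):
            taxa = [tid for tid in otu.taxon_ids
                    if tid in tax.data.index and tax.domain_of(tid) == dom]
            if taxa:
                domain_tables[dom] = otu.select_taxa(taxa)
        if not domain_tables:
            raise ValueError("no taxa with a recognised domain")
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    summary["stages"]["load"] = {
        "n_samples": otu.n_samples, "n_taxa": otu.n_taxa,
        "domains": {d: t.n_taxa for d, t in domain_tables.items()},
    }
    angles = _usable_angles(meta, cfg.angles, cfg.min_group_samples)
    summary["angles"] = angles

    # ---- beta diversity --------------------------------------------------
    try:
        for dom, table in domain_tables.items():
            dom_dir = out_root / dom.lower()
            dom_dir.mkdir(exist_ok=True)
            rel = to_relative(table)
            d_bc = bd.bray_curtis(rel)
            ord_res = bd.nmds(d_bc, k=cfg.nmds_k, n_restarts=cfg.nmds_restarts,
                              seed=seeds["beta"])
            _write_tsv(ord_res.coordinates, dom_dir / "nmds.tsv")
            rows = []
            for angle in angles:
                g = assign_groups(meta, angle)
                try:
                    an = bd.anosim(d_bc, g, n_perm=cfg.n_perm, seed=seeds["beta"])
                    disp = bd.dispersion_test(d_bc, g, n_perm=cfg.n_perm,
                                              seed=seeds["beta"])
                except ValueError as exc:
                    logger.info("%s %s group tests skipped: %s", dom, angle, exc)
                    continue
                rows.append(dict(angle=angle,
                                 anosim_R=an.statistic, anosim_p=an.p_value,
                                 dispersion_F=disp.statistic,
                                 dispersion_p=disp.p_value))
            _write_tsv(pd.DataFrame(rows).set_index("angle")
                       if rows else pd.DataFrame(), dom_dir / "group_tests.tsv")
            summary["stages"].setdefault("beta_diversity", {})[dom] = {
                "stress": ord_res.stress, "n_group_tests": len(rows),
            }
            # regional distance decay: sites carrying all three stages
            stage_sets = meta.data.groupby("site_id")["stage"].agg(set)
            regional = sorted(s for s, st in stage_sets.items()
                              if st >= {"A", "C", "M"})
            if len(regional) >= 3:
                geo_pts, succ_pts = bd.site_pair_statistics(
                    table, meta, sites=regional,
                    statistic=cfg.decay_statistic,
                    n_perm=min(cfg.n_perm, 199), seed=seeds["decay"])
                if len(geo_pts) >= 3:
                    reg = bd.distance_decay(geo_pts, succ_pts)
                    decay = {
                        "geography": dataclasses.asdict(reg.geography),
                        "succession": dataclasses.asdict(reg.succession),
                        "intersection_km": reg.intersection_km,
                        "sites": regional,
                    }
                    (dom_dir / "distance_decay.json").write_text(
                        json.dumps(decay, indent=2, sort_keys=True))
                    summary["stages"].setdefault("distance_decay", {})[dom] = \
                        reg.intersection_km
    except StageError:
        raise
    except Exception as exc:
        raise StageError("beta_diversity", str(exc)) from exc

    # ---- mediation screen ------------------------------------------------
    try:
        for dom, table in domain_tables.items():
            dom_dir = out_root / dom.lower()
            phylum = med.phylum_table(table, tax, min_mean_rel=cfg.min_mean_rel)
            frames = []
            for angle in angles:
                g = assign_groups(meta, angle)
                screen = med.mantel_screen(
                    phylum, env, g, n_perm=cfg.n_perm,
                    seed=seeds["mediation"], domain=dom,
                    min_samples=cfg.min_group_samples)
                lf = screen.long_format()
                lf.insert(1, "angle", angle)
                frames.append(lf)
            screen_df = pd.concat(frames, ignore_index=True)
            _write_tsv(screen_df.set_index(["angle", "group", "variable"]),
                       dom_dir / "mantel_screen.tsv")
            summary["stages"].setdefault("mediation", {})[dom] = len(screen_df)
    except Exception as exc:
        raise StageError("mediation", str(exc)) from exc

    # ---- assembly (needs the tree) ----------------------------------------
    pooled_fractions: dict[str, list] = {}
    group_samples: dict[str, list] = {}
    try:
        tree_path = in_dir / "tree.nwk"
        if not tree_path.exists():
            raise FileNotFoundError(f"missing tree file: {tree_path}")
        tree = read_tree(tree_path)
        for dom, table in domain_tables.items():
            dom_dir = out_root / dom.lower()
            results = []
            for angle in angles:
                per_level = asm.assembly_by_angle(
                    table, tree, meta, angle,
                    n_null=cfg.n_null, seed=seeds["assembly"],
                    bnti_threshold=cfg.bnti_threshold,
                    rc_threshold=cfg.rc_threshold)
                g = assign_groups(meta, angle)
                for pf in per_level:
                    label = f"{angle}:{pf.group}"
                    results.append(dataclasses.replace(pf, group=label))
                    group_samples[label] = g.level_samples(pf.group)
            if results:
                _write_tsv(asm.fractions_table(results),
                           dom_dir / "process_fractions.tsv")
                pooled_fractions[dom] = results
            summary["stages"].setdefault("assembly", {})[dom] = len(results)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("assembly", str(exc)) from exc

    # ---- co-occurrence networks -------------------------------------------
    try:
        if len(domain_tables) == 2:
            filt = {dom: cumulative_abundance_filter(tab, cfg.coverage)
                    for dom, tab in domain_tables.items()}
            net_dir = out_root / "network"
            net_dir.mkdir(exist_ok=True)
            for angle in angles:
                g = assign_groups(meta, angle)
                results = net.network_by_group(
                    filt["Bacteria"], filt["Eukaryota"], tax, g,
                    min_samples=cfg.min_group_samples,
                    rho_threshold=cfg.rho_threshold)
                if results:
                    _write_tsv(net.topology_table(results),
                               net_dir / f"topology_{angle}.tsv")
                    for level, (graph, _) in results.items():
                        _write_tsv(graph.edge_table(),
                                   net_dir / f"edges_{angle}_{level}.tsv")
                summary["stages"].setdefault("network", {})[angle] = \
                    {lvl: m.as_series().to_dict() for lvl, (gr, m) in results.items()}
        else:
            logger.info("network stage skipped: need both domains")
    except Exception as exc:
        raise StageError("network", str(exc)) from exc

    # ---- sorting-environment correlations ---------------------------------
    try:
        if pooled_fractions and len(group_samples) >= 3:
            sc = med.sorting_env_correlation(pooled_fractions, env, group_samples)
            _write_tsv(sc.table, out_root / "sorting_correlation.tsv")
            summary["stages"]["sorting"] = {
                "opposed_variables": sc.opposition_report(
                    tuple(pooled_fractions) if len(pooled_fractions) == 2
                    else ("Bacteria", "Eukaryota")),
            }
    except Exception as exc:
        raise StageError("sorting", str(exc)) from exc

    manifest = {
        "config": {**dataclasses.asdict(cfg), "angles": list(cfg.angles)},
        "stage_seeds": seeds,
        "summary": summary,
    }
    (out_root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return manifest
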