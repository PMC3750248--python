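"""Panel orchestration: all-pairs relatedness across a genome panel.

A declarative config (dict, or YAML on disk) lists the genomes and
every threshold; ``run_panel`` executes homology -> relatedness ->
synteny for each of the n(n-1)/2 pairs (plus completeness and island
detection when marker/DNA inputs are given), writes one TSV per
statistic and a JSON metadata file, and returns the matrices in
memory. Per-pair ortholog tables are cached under ``pairs/`` so an
interrupted run resumes without recomputing finished pairs.
"""
from __future__ import annotations

import itertools
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .completeness import estimate_completeness
from .homology import orthologs_between
from .io_formats import (
    read_fasta,
    read_gene_table,
    read_ortholog_table,
    write_ortholog_table,
)
from .islands import annotate_composition, find_islands
from .model import GenomeRecord
from .relatedness import compute_aai, compute_ortholog_fraction
from .synteny import find_synteny_blocks, synteny_metrics

logger = logging.getLogger("pairplasma")

DEFAULT_THRESHOLDS = {
    "evalue_max": 1e-5,
    "cov_min": 0.7,
    "pident_min": 0.0,
    "gap_tolerance": 1,
    "min_block_size": 2,
    "allow_inversion": True,
    "min_run": 5,
    "max_panel_hits": 0,
    "marker_evalue_max": 1e-10,
    "marker_cov_min": 0.7,
}


@dataclass
class PanelGenome:
    genome_id: str
    genome: GenomeRecord
    proteins: dict[str, str]
    gene_dna: Optional[dict[str, str]] = None


@dataclass
class PanelReport:
    aai: pd.DataFrame
    ortholog_fraction: pd.DataFrame
    n_orthologs: pd.DataFrame
    synteny_fraction: pd.DataFrame
    mean_block_length: pd.DataFrame
    completeness: Optional[pd.DataFrame] = None
    islands: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _load_panel_from_config(config: dict) -> list[PanelGenome]:
    genomes_cfg = config.get("genomes", [])
    if len(genomes_cfg) < 2:
        raise ValueError("panel config must list at least 2 genomes")
    # fail fast: validate every input path before any computation
    for g in genomes_cfg:
        for key in ("proteins", "genes", "dna"):
            p = g.get(key)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"genome {g.get('id')}: missing {key} file {p}")
    panel = []
    for g in genomes_cfg:
        genome = read_gene_table(
            g["genes"],
            dialect=g.get("dialect", "tsv"),
            genome_id=g.get("id"),
        )
        proteins = read_fasta(g["proteins"], alphabet="protein")
        gene_dna = None
        if g.get("dna"):
            gene_dna = read_fasta(g["dna"], alphabet="dna")
        panel.append(
            PanelGenome(
                genome_id=g.get("id", genome.genome_id),
                genome=genome,
                proteins=proteins,
                gene_dna=gene_dna,
            )
        )
    return panel


def run_panel(
    config: dict,
    out_dir: Optional[str] = None,
    panel: Optional[list[PanelGenome]] = None,
    force: bool = False,
) -> PanelReport:
    """Execute the all-pairs pipeline over a genome panel.

    ``panel`` may be passed directly (in-memory objects); otherwise the
    genomes are loaded from the config's file paths. When ``out_dir``
    is given, matrices are written as TSV and per-pair ortholog tables
    are cached there.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    if panel is None:
        panel = _load_panel_from_config(config)
    ids = [g.genome_id for g in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids in the panel must be unique")

    pair_dir = None
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        pair_dir = os.path.join(out_dir, "pairs")
        os.makedirs(pair_dir, exist_ok=True)

    mats = {
        name: pd.DataFrame(math.nan, index=ids, columns=ids, dtype=float)
        for name in ("aai", "ortholog_fraction", "n_orthologs", "synteny_fraction", "mean_block_length")
    }
    for g in panel:
        mats["aai"].loc[g.genome_id, g.genome_id] = 100.0
        mats["ortholog_fraction"].loc[g.genome_id, g.genome_id] = 1.0
        mats["n_orthologs"].loc[g.genome_id, g.genome_id] = g.genome.n_genes
        mats["synteny_fraction"].loc[g.genome_id, g.genome_id] = 1.0

    orthomaps: dict[tuple[str, str], object] = {}
    for ga, gb in itertools.combinations(panel, 2):
        cache = (
            os.path.join(pair_dir, f"{ga.genome_id}__{gb.genome_id}.orthologs.tsv")
            if pair_dir
            else None
        )
        if cache and os.path.exists(cache) and not force:
            logger.info("pair %s~%s: reusing cached orthologs", ga.genome_id, gb.genome_id)
            om = read_ortholog_table(cache)
        else:
            logger.info("pair %s~%s: aligning proteomes", ga.genome_id, gb.genome_id)
            om = orthologs_between(
                ga.proteins,
                gb.proteins,
                genome_a_id=ga.genome_id,
                genome_b_id=gb.genome_id,
                evalue_max=thresholds["evalue_max"],
                cov_min=thresholds["cov_min"],
                pident_min=thresholds["pident_min"],
            )
            if cache:
                write_ortholog_table(om, cache)
        logger.debug("pair %s~%s: %d ortholog pairs", ga.genome_id, gb.genome_id, len(om.pairs))
        orthomaps[(ga.genome_id, gb.genome_id)] = om

        blocks = find_synteny_blocks(
            om,
            ga.genome,
            gb.genome,
            gap_tolerance=thresholds["gap_tolerance"],
            min_block_size=thresholds["min_block_size"],
            allow_inversion=thresholds["allow_inversion"],
        )
        frac, mean_len = synteny_metrics(blocks, om)
        a, b = ga.genome_id, gb.genome_id
        aai = compute_aai(om) if om.pairs else math.nan
        mats["aai"].loc[a, b] = mats["aai"].loc[b, a] = aai
        of = compute_ortholog_fraction(om)
        mats["ortholog_fraction"].loc[a, b] = mats["ortholog_fraction"].loc[b, a] = of
        mats["n_orthologs"].loc[a, b] = mats["n_orthologs"].loc[b, a] = len(om.pairs)
        mats["synteny_fraction"].loc[a, b] = mats["synteny_fraction"].loc[b, a] = frac
        mats["mean_block_length"].loc[a, b] = mats["mean_block_length"].loc[b, a] = mean_len

    completeness_df = None
    markers_path = config.get("markers")
    if markers_path:
        marker_refs = read_fasta(markers_path, alphabet="protein")
        rows = []
        for g in panel:
            rep = estimate_completeness(
                g.proteins,
                marker_refs,
                genome_id=g.genome_id,
                evalue_max=thresholds["marker_evalue_max"],
                cov_min=thresholds["marker_cov_min"],
            )
            rows.append(
                {
                    "genome": g.genome_id,
                    "n_markers": rep.n_markers,
                    "n_found": rep.n_found,
                    "completeness_pct": round(rep.completeness_pct, 2),
                }
            )
        completeness_df = pd.DataFrame(rows)

    islands_df = None
    if config.get("islands", True) and len(panel) >= 2:
        rows = []
        for g in panel:
            maps = [
                om
                for (a, b), om in orthomaps.items()
                if g.genome_id in (a, b)
            ]
            calls = find_islands(
                g.genome,
                maps,
                min_run=thresholds["min_run"],
                max_panel_hits=thresholds["max_panel_hits"],
            )
            if g.gene_dna:
                annotate_composition(calls, g.genome, g.gene_dna)
            for c in calls:
                rows.append(
                    {
                        "genome": c.genome_id,
                        "contig": c.contig_id,
                        "start_ordinal": c.start_ordinal,
                        "end_ordinal": c.end_ordinal,
                        "n_genes": c.n_genes,
                        "gc_island": c.gc_island,
                        "gc_z": c.gc_z,
                        "gc_skew": c.gc_skew,
                    }
                )
        islands_df = pd.DataFrame(
            rows,
            columns=["genome", "contig", "start_ordinal", "end_ordinal", "n_genes", "gc_island", "gc_z", "gc_skew"],
        )

    meta = {
        "tool": "pairplasma",
        "version": __version__,
        "thresholds": thresholds,
        "genomes": ids,
        "n_pairs": len(orthomaps),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    report = PanelReport(
        aai=mats["aai"],
        ortholog_fraction=mats["ortholog_fraction"],
        n_orthologs=mats["n_orthologs"],
        synteny_fraction=mats["synteny_fraction"],
        mean_block_length=mats["mean_block_length"],
        completeness=completeness_df,
        islands=islands_df,
        meta=meta,
    )
    if out_dir:
        for name, df in mats.items():
            df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t")
        if completeness_df is not None:
            completeness_df.to_csv(os.path.join(out_dir, "completeness.tsv"), sep="\t", index=False)
        if islands_df is not None:
            islands_df.to_csv(os.path.join(out_dir, "islands.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "run_meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
    return report
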