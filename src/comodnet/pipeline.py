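"""End-to-end orchestration: simulate -> preprocess -> DE -> modules -> integrate -> network.

Each stage is a plain function over in-memory objects; :func:`run_all` wires
them together, writes every stage output as TSV/GraphML/SIF under an output
directory, and emits a run manifest (config hash, seed, input checksums,
package version, timestamps). Identical configurations and seeds reproduce
byte-identical TSV outputs; only the manifest carries timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import coexpression as cx
from . import diffexpr as de
from . import integration as integ
from . import io as cio
from . import network as net
from .config import PipelineConfig
from .design import StudyDesign, generate_design
from .errors import ComodnetError
from .matrix import ExpressionMatrix
from .preprocess import preprocess_pipeline
from .simulate import (
    default_mirna_modules,
    default_protein_modules,
    default_repression_map,
    simulate_annotation_tables,
    simulate_paired_omics,
)

log = logging.getLogger("comodnet")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    input_checksums: dict
    started: str
    finished: str
    outputs: list

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(ComodnetError):
    """An error tagged with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except ComodnetError as exc:
                raise StageError(name, exc) from exc
            except OSError as exc:
                raise StageError(name, exc) from exc

        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper

    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig):
    """Generate design, paired omics and annotation tables from the config."""
    design = generate_design(cfg.n_per_group, seed=cfg.seed)
    mirna_mods = default_mirna_modules()
    prot_mods = default_protein_modules()
    repression = default_repression_map()
    mirna, protein = simulate_paired_omics(
        design,
        mirna_mods,
        prot_mods,
        repression,
        seed=cfg.seed,
        n_mirna_features=cfg.n_mirna_features,
        n_protein_features=cfg.n_protein_features,
        noise_sd=cfg.noise_sd,
        n_replicates=cfg.n_replicates,
        flag_rate=cfg.flag_rate,
        replicate_noise_sd=cfg.replicate_noise_sd,
    )
    targets, ppi = simulate_annotation_tables(
        repression,
        mirna_mods,
        prot_mods,
        n_decoy_targets=cfg.n_decoy_targets,
        ppi_density=cfg.ppi_density,
        seed=cfg.seed + 1,
        n_mirna_features=cfg.n_mirna_features,
        n_protein_features=cfg.n_protein_features,
    )
    return design, mirna, protein, targets, ppi


@_stage("load")
def stage_load(cfg: PipelineConfig):
    """Load external inputs named in the config."""
    design = cio.read_design_tsv(cfg.design_tsv)
    mirna = cio.read_expression_tsv(cfg.mirna_tsv)
    protein = cio.read_expression_tsv(cfg.protein_tsv)
    targets = cio.read_table_tsv(cfg.targets_tsv)
    ppi = cio.read_table_tsv(cfg.ppi_tsv)
    return design, mirna, protein, targets, ppi


@_stage("preprocess")
def stage_preprocess(cfg: PipelineConfig, mirna: ExpressionMatrix, protein: ExpressionMatrix):
    mirna_p = preprocess_pipeline(mirna, cfg.max_missing_fraction)
    protein_p = preprocess_pipeline(protein, cfg.max_missing_fraction)
    return mirna_p, protein_p


@_stage("de")
def stage_de(cfg: PipelineConfig, m: ExpressionMatrix, design: StudyDesign):
    tables = de.moderated_de_tables(m, design)
    summary = de.directional_summary(
        tables, fc_lo=cfg.fc_threshold, p_thresh=cfg.p_threshold, n_total=len(m.values)
    )
    return tables, summary


@_stage("wgcna")
def stage_coexpression(cfg: PipelineConfig, m: ExpressionMatrix, design: StudyDesign):
    partition, report = cx.coexpression_modules(
        m,
        beta=cfg.beta,
        cut_height=cfg.cut_height,
        deep_split=cfg.deep_split,
        min_module_size=cfg.min_module_size,
        dissimilarity=cfg.dissimilarity,
        power_candidates=range(cfg.beta_min, cfg.beta_max + 1),
    )
    eigengenes = cx.eigengene_matrix(m, partition)
    traits = integ.trait_frame(design)
    module_trait = cx.module_trait_table(eigengenes, traits) if len(eigengenes.values) else pd.DataFrame(columns=["module", "trait", "r", "p"])
    gs = cx.feature_significance(m, integ.encode_eoc(design))
    return partition, report, eigengenes, module_trait, gs


@_stage("integrate")
def stage_integrate(
    cfg: PipelineConfig,
    design: StudyDesign,
    mirna: ExpressionMatrix,
    protein: ExpressionMatrix,
    me_mirna: cx.EigengeneMatrix,
    me_protein: cx.EigengeneMatrix,
    gs_mirna: pd.DataFrame,
    gs_protein: pd.DataFrame,
    partition_protein,
):
    eoc = integ.encode_eoc(design)
    traits = integ.trait_frame(design)
    prot_traits = integ.select_trait_features(
        gs_protein, cfg.trait_p_max, cfg.trait_r_min, cfg.top_k
    )
    mirna_traits = integ.select_trait_features(
        gs_mirna, cfg.trait_p_max, cfg.trait_r_min, cfg.top_k
    )
    mirna_side = traits.join(protein.values.loc[prot_traits].T) if prot_traits else traits
    protein_side = traits.join(mirna.values.loc[mirna_traits].T) if mirna_traits else traits
    cross_mirna = (
        integ.cross_omic_table(me_mirna, mirna_side, eoc)
        if len(me_mirna.values)
        else pd.DataFrame(columns=["module", "trait", "r", "p", "concordance_vs_eoc"])
    )
    cross_protein = (
        integ.cross_omic_table(me_protein, protein_side, eoc)
        if len(me_protein.values)
        else pd.DataFrame(columns=["module", "trait", "r", "p", "concordance_vs_eoc"])
    )
    anti = integ.anti_correlation_report(
        me_mirna,
        me_protein,
        eoc,
        r_screen=cfg.r_screen,
        protein_expr=protein,
        partition_protein=partition_protein,
    )
    return cross_mirna, cross_protein, anti


@_stage("network")
def stage_network(
    cfg: PipelineConfig,
    de_mirna: pd.DataFrame,
    de_protein: pd.DataFrame,
    mirna: ExpressionMatrix,
    protein: ExpressionMatrix,
    targets: pd.DataFrame,
    ppi: pd.DataFrame,
):
    """Assemble and score the integrative network for the configured region.

    Eligibility uses the dependent-vs-naive comparison tables; coexpression
    edges come from feature-level miRNA-protein correlations among eligible
    features, filtered with the region's coexpression thresholds.
    """
    elig_mirna, elig_protein = net.filter_de_evidence(de_mirna, de_protein, cfg.region)
    pairs = []
    for a in elig_mirna["feature_id"]:
        if a not in mirna.values.index:
            continue
        xa = mirna.values.loc[a]
        for b in elig_protein["feature_id"]:
            if b not in protein.values.index:
                continue
            r, p = cx.correlation_with_p(xa, protein.values.loc[b])
            pairs.append({"node_a": a, "node_b": b, "r": r, "p": p})
    coexpr = pd.DataFrame(pairs, columns=["node_a", "node_b", "r", "p"])
    coexpr_ok = net.filter_coexpr_evidence(coexpr, cfg.region) if len(coexpr) else coexpr
    g = net.assemble_network(
        elig_mirna, elig_protein, targets, ppi, coexpr_ok, ppi_min=cfg.ppi_min, region=cfg.region
    )
    scores = net.topology_scores(g)
    top, ranked = net.hub_report(scores, k=cfg.hub_k)
    return g, scores, top, ranked


def run_all(cfg: PipelineConfig, outdir) -> RunManifest:
    """Run the full pipeline and write every stage output under ``outdir``."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("config: %s", json.dumps(cfg.to_dict(), sort_keys=True))

    external = cfg.mirna_tsv is not None
    checksums = {}
    if external:
        for key in ("mirna_tsv", "protein_tsv", "design_tsv", "targets_tsv", "ppi_tsv"):
            path = getattr(cfg, key)
            if path:
                checksums[key] = _sha256(path)
        design, mirna, protein, targets, ppi = stage_load(cfg)
    else:
        design, mirna, protein, targets, ppi = stage_simulate(cfg)

    cio.write_design_tsv(design, out / "design.tsv")
    cio.write_expression_tsv(mirna, out / "mirna_raw.tsv")
    cio.write_expression_tsv(protein, out / "protein_raw.tsv")
    cio.write_table_tsv(targets, out / "targets.tsv")
    cio.write_table_tsv(ppi, out / "ppi.tsv")

    mirna_p, protein_p = stage_preprocess(cfg, mirna, protein)
    cio.write_expression_tsv(mirna_p, out / "mirna_preprocessed.tsv")
    cio.write_expression_tsv(protein_p, out / "protein_preprocessed.tsv")

    de_out = {}
    for label, m in (("mirna", mirna_p), ("protein", protein_p)):
        tables, summary = stage_de(cfg, m, design)
        de_out[label] = tables
        for contrast, tab in tables.items():
            cio.write_table_tsv(tab, out / f"de_{label}_{contrast}.tsv")
        cio.write_table_tsv(summary, out / f"de_{label}_summary.tsv")

    wg = {}
    for label, m in (("mirna", mirna_p), ("protein", protein_p)):
        partition, report, eigengenes, module_trait, gs = stage_coexpression(cfg, m, design)
        wg[label] = (partition, eigengenes, gs)
        assign = pd.DataFrame(
            {
                "feature_id": partition.labels.index,
                "module": partition.labels.values,
                "color": [partition.colors[v] for v in partition.labels.values],
            }
        )
        cio.write_table_tsv(assign, out / f"modules_{label}.tsv")
        eg = eigengenes.values.reset_index(names="module")
        cio.write_table_tsv(eg, out / f"eigengenes_{label}.tsv")
        cio.write_table_tsv(report.table, out / f"softpower_{label}.tsv")
        cio.write_table_tsv(module_trait, out / f"module_trait_{label}.tsv")
        cio.write_table_tsv(gs, out / f"gs_{label}.tsv")
        log.info(
            "%s: beta=%d signed_r2=%.3f modules=%d",
            label, report.selected_beta, report.achieved_r2, len(partition.module_ids),
        )

    cross_mirna, cross_protein, anti = stage_integrate(
        cfg, design, mirna_p, protein_p,
        wg["mirna"][1], wg["protein"][1], wg["mirna"][2], wg["protein"][2], wg["protein"][0],
    )
    cio.write_table_tsv(cross_mirna, out / "cross_omic_mirna_modules.tsv")
    cio.write_table_tsv(cross_protein, out / "cross_omic_protein_modules.tsv")
    cio.write_table_tsv(anti, out / "anti_correlation_pairs.tsv")

    g, scores, top, ranked = stage_network(
        cfg, de_out["mirna"]["CIEvsNaive"], de_out["protein"]["CIEvsNaive"],
        mirna_p, protein_p, targets, ppi,
    )
    cio.write_graph(g, out / "network.graphml", out / "network.sif")
    cio.write_table_tsv(ranked, out / "node_scores.tsv")

    finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    outputs = sorted({p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"})
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        seed=cfg.seed,
        version=__version__,
        input_checksums=checksums,
        started=started,
        finished=finished,
        outputs=outputs,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
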