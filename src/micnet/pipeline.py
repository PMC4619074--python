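"""End-to-end orchestration: cohort -> per-platform prep -> differential
analysis -> fusion -> all-pairs correlation -> network/hubs -> enrichment,
with per-stage outputs, drop-count logging and a provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import MicParams, all_pairs
from .blocks import ValidationError
from .cohort import CohortSpec, SyntheticCohort, generate_cohort, read_cohort, reduced_spec
from .differential import fold_change_ddct, hcluster, nb_test, welch_test_dct
from .enrichment import RegulatorAnnotation, hypergeom_enrich, random_control_filter, read_gmt
from .fusion import EncodingConfig, build_fused_matrix, encode_genotype_block, \
    encode_phenotypes, subset_samples
from .network import NetworkConfig, build_network, filter_edges, find_hubs, \
    hub_gene_list, write_edge_tsv, write_graphml
from .prep import apply_negative_background, filter_methylation_loci, \
    normalize_delta_ct, normalize_mirna_positive

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str = "micnet_out"
    seed: int = 0
    cohort_dir: str | None = None  # read an existing cohort instead of generating
    reduced: bool = True  # unit-scale synthetic cohort (full study scale if False)
    fail_fraction: float = 0.25
    detection_alpha: float = 0.05
    drop_x: bool = True
    negative_quantile: float = 0.75
    mirna_group_a: list[str] = field(default_factory=lambda: ["yst"])
    stemcell_a: str = "yst"
    stemcell_b: str = "dysgerminoma"
    mic: MicParams = field(default_factory=MicParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    repeat_without: str | None = "yst"
    gmt: str | None = None
    enrichment_seed_offset: int = 101

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "mic" in kwargs:
            kwargs["mic"] = MicParams(**kwargs["mic"])
        if "network" in kwargs:
            kwargs["network"] = NetworkConfig(**kwargs["network"])
        if "encoding" in kwargs:
            kwargs["encoding"] = EncodingConfig(**kwargs["encoding"])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fuse_cohort(cohort: SyntheticCohort, config: PipelineConfig | None = None):
    """Prep every platform of a cohort and fuse: returns (fused, qc_report).

    Convenience wrapper over the individual stages with default parameters.
    """
    config = config or PipelineConfig()
    meth, qc = filter_methylation_loci(
        cohort.methylation, cohort.detection_p,
        fail_fraction=config.fail_fraction,
        detection_alpha=config.detection_alpha, drop_x=config.drop_x)
    mirna = normalize_mirna_positive(cohort.mirna)
    mirna, _ = apply_negative_background(mirna, quantile=config.negative_quantile)
    dct = normalize_delta_ct(cohort.stemcell)
    phen = encode_phenotypes(cohort.annotations, config.encoding)
    geno = encode_genotype_block(cohort.genotypes, config.encoding)
    fused = build_fused_matrix([meth, mirna, dct, geno, phen])
    return fused, qc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "outputs": {}}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # --- stage: cohort ---
    if config.cohort_dir:
        cohort = read_cohort(config.cohort_dir)
    else:
        spec = reduced_spec(seed=config.seed) if config.reduced \
            else CohortSpec(seed=config.seed)
        cohort = generate_cohort(spec)
    manifest["stages"]["cohort"] = {
        "n_samples": len(cohort.annotations),
        "n_cpg": len(cohort.methylation.values),
        "n_mirna_rows": len(cohort.mirna.values),
        "n_stemcell_rows": len(cohort.stemcell.values),
    }

    # --- stage: methylation QC ---
    meth, qc = filter_methylation_loci(
        cohort.methylation, cohort.detection_p,
        fail_fraction=config.fail_fraction,
        detection_alpha=config.detection_alpha, drop_x=config.drop_x)
    qc_path = out / "methylation_qc.json"
    qc_path.write_text(json.dumps(qc.to_dict(), indent=1))
    record("methylation_qc", qc_path)
    manifest["stages"]["methylation_qc"] = {
        "n_input": qc.n_input_loci, "n_detection_removed": qc.n_detection_removed,
        "n_x_removed": qc.n_x_removed, "n_retained": qc.n_retained}

    # --- stage: miRNA normalization ---
    mirna = normalize_mirna_positive(cohort.mirna)
    mirna, below = apply_negative_background(mirna, quantile=config.negative_quantile)
    p = out / "mirna_normalized.tsv"
    mirna.write_tsv(p)
    record("mirna_normalized", p)
    manifest["stages"]["mirna_norm"] = {
        "n_below_background": int(below.fillna(False).to_numpy().sum())}

    # --- stage: miRNA differential expression ---
    hist = cohort.annotations["histology"]
    complete_mirna = sorted(mirna.noncontrol().complete_samples())
    groups = pd.Series(
        ["a" if hist[s] in config.mirna_group_a else "b" for s in complete_mirna],
        index=complete_mirna)
    counts = mirna.noncontrol().values[complete_mirna]
    de = nb_test(counts, groups, round_counts=True)
    p = out / "mirna_de.tsv"
    de.to_csv(p, sep="\t")
    record("mirna_de", p)
    manifest["stages"]["mirna_de"] = {
        "n_features": len(de), "n_q_lt_05": int((de["q_value"] < 0.05).sum()),
        "n_samples": len(complete_mirna)}

    # --- stage: stem-cell delta-Ct, fold change, clustering ---
    dct = normalize_delta_ct(cohort.stemcell)
    p = out / "stemcell_dct.tsv"
    dct.write_tsv(p)
    record("stemcell_dct", p)
    complete_sc = sorted(dct.complete_samples())
    ga = [s for s in complete_sc if hist[s] == config.stemcell_a]
    gb = [s for s in complete_sc if hist[s] == config.stemcell_b]
    fc_rows, welch_p = [], None
    if len(ga) >= 2 and len(gb) >= 2:
        fc = fold_change_ddct(dct, ga, gb)
        welch_p = welch_test_dct(dct, ga, gb)
        fc_rows = [
            {"gene_id": r.gene_id, "delta_delta_ct": r.delta_delta_ct,
             "fold_change": r.fold_change, "log2_fold": r.log2_fold,
             "passes_3fold": r.passes_3fold, "welch_p": float(welch_p[r.gene_id])}
            for r in fc]
        p = out / "stemcell_foldchange.tsv"
        pd.DataFrame(fc_rows).to_csv(p, sep="\t", index=False)
        record("stemcell_foldchange", p)
    dend = hcluster(dct.values)
    p = out / "stemcell_dendrogram.nwk"
    p.write_text(dend.to_newick() + "\n")
    record("stemcell_dendrogram", p)
    manifest["stages"]["stemcell"] = {
        "n_genes": len(dct.values), "n_samples": len(complete_sc),
        "n_3fold": sum(1 for r in fc_rows if r["passes_3fold"]),
        "n_welch_p_lt_05": sum(1 for r in fc_rows if r["welch_p"] < 0.05)}

    # --- stage: fusion ---
    phen = encode_phenotypes(cohort.annotations, config.encoding)
    geno = encode_genotype_block(cohort.genotypes, config.encoding)
    fused = build_fused_matrix([meth, mirna, dct, geno, phen])
    p = out / "fused.tsv"
    fused.write_tsv(p)
    record("fused", p)
    manifest["stages"]["fusion"] = {
        "n_rows": fused.n_features, "n_samples": len(fused.sample_ids)}

    manifest["stages"].update(_correlate_and_network(
        fused, config, out, suffix=""))

    if config.repeat_without:
        sub = subset_samples(fused, config.repeat_without,
                             annotations=cohort.annotations)
        manifest["stages"].update(_correlate_and_network(
            sub, config, out, suffix=f"_non{config.repeat_without}"))

    # --- stage: enrichment (needs an annotation source) ---
    hub_genes_path = out / "hub_genes.txt"
    if hub_genes_path.exists() and config.gmt:
        gene_list = [g for g in hub_genes_path.read_text().split() if g]
        universe = set(fused.gene_symbols[fused.gene_symbols != ""])
        if gene_list:
            annotation = RegulatorAnnotation(read_gmt(config.gmt), universe)
            results = hypergeom_enrich(gene_list, annotation)
            results = random_control_filter(
                results, annotation, list_size=len(set(gene_list) & universe),
                seed=config.seed + config.enrichment_seed_offset)
            p = out / "enrichment.tsv"
            pd.DataFrame([vars(r) for r in results]).to_csv(p, sep="\t", index=False)
            record("enrichment", p)
            manifest["stages"]["enrichment"] = {
                "n_regulators": len(results),
                "n_significant_after_control": sum(
                    r.significant_after_control for r in results)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _correlate_and_network(fused, config: PipelineConfig, out: Path,
                           suffix: str) -> dict:
    pairs = all_pairs(fused, config.mic)
    p = out / f"pairs{suffix}.tsv"
    pairs.to_csv(p, sep="\t", index=False, float_format="%.6g")
    edges = filter_edges(pairs, config.network)
    net = build_network(edges)
    write_graphml(net, out / f"network{suffix}.graphml")
    write_edge_tsv(net, out / f"edges{suffix}.tsv")
    report = find_hubs(net, config.network)
    hubs_path = out / f"hubs{suffix}.json"
    hubs_path.write_text(json.dumps(
        {"hubs": report.hubs, "neighbors": report.neighbors,
         "degrees": report.degrees}, indent=1, sort_keys=True))
    genes = hub_gene_list(report, fused.gene_symbols)
    (out / f"hub_genes{suffix}.txt").write_text("\n".join(genes) + ("\n" if genes else ""))
    return {f"correlation{suffix}": {"n_pairs": len(pairs), "n_edges": len(edges)},
            f"network{suffix}": {"n_nodes": net.number_of_nodes(),
                                 "n_components": len({d.get("component")
                                                      for _, d in net.nodes(data=True)}),
                                 "n_hubs": len(report), "hub_genes": genes}}
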