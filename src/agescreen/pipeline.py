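"""End-to-end pipeline orchestration from a single YAML config.

Stages run in dependency order:

1. screen (Spearman vs age, per region, expression and methylation)
2. calibrate (permutation cutoff; pipeline cutoff = max over regions, or a
   fixed ``cutoff`` from the config)
3. consensus (cross-region, sign-consistent, both data kinds)
4. map-sites (methylation sites -> genes through promoter windows)
5. union (aging genes = expression consensus | methylation-derived genes)
6. tf-predict (top-|r| input ranking, per-region enrichment, TF consensus,
   coverage filter, TF age-profile check)
7. modules (correlation-distance clustering + annotation enrichment)
8. network (co-expressed neighbors -> regulator enrichment -> edges)
9. overlap (aging vs disease gene lists; shared pathways)

Every stage writes plain TSV/JSON into the output directory and a manifest
records parameters, seeds and input checksums, so any stage can be rerun or
inspected standalone.
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
from .consensus import consensus_across_regions, map_sites_to_genes, union_aging_genes
from .disease import gene_set_overlap, shared_pathways
from .enrichment import (
    predict_tfs_per_region,
    rank_and_select_top,
    target_coverage_filter,
    tf_age_profile_check,
    tf_consensus,
)
from .errors import ConfigError
from .io import (
    FLOAT_FMT,
    read_bed,
    read_gene_list,
    read_gmt,
    read_matrix,
    read_phenotype,
)
from .modules import correlation_distance, detect_modules, module_enrichment
from .network import build_network
from .screen import (
    DEFAULT_CUTOFF,
    calibrate_cutoff,
    screen_features,
    spearman_age_correlation,
)

logger = logging.getLogger(__name__)

STAGES = (
    "screen",
    "calibrate",
    "consensus",
    "map_sites",
    "union",
    "tf_predict",
    "modules",
    "network",
    "overlap",
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (paths + parameters)."""

    regions: dict  # region -> {expression, methylation, phenotype} paths
    annotations: dict = field(default_factory=dict)  # motif/literature/go/pathways GMTs
    intervals: dict = field(default_factory=dict)  # sites/tss (BED)
    ad_genes: str | None = None
    network_genes: str | None = None
    seed: int | None = None
    universe_n: int | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(
            regions=raw.get("regions", {}),
            annotations=raw.get("annotations", {}),
            intervals=raw.get("intervals", {}),
            ad_genes=raw.get("ad_genes"),
            network_genes=raw.get("network_genes"),
            seed=raw.get("seed"),
            universe_n=raw.get("universe_n"),
            params=raw.get("params", {}),
        )
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        if not self.regions:
            raise ConfigError("config lists no regions")
        if self.universe_n is None:
            raise ConfigError("universe_n is required (never defaulted)")
        calibrate = self.params.get("calibrate", True)
        if calibrate and self.seed is None:
            raise ConfigError("seed is mandatory when calibration runs")

        def resolve(p: str) -> str:
            q = Path(p)
            if base is not None and not q.is_absolute():
                q = base / q
            if not q.exists():
                raise ConfigError(f"input path does not exist: {q}")
            return str(q)

        for region, paths in self.regions.items():
            for key in ("expression", "methylation", "phenotype"):
                if key in paths:
                    paths[key] = resolve(paths[key])
            if "phenotype" not in paths:
                raise ConfigError(f"region {region}: phenotype path required")
        for d in (self.annotations, self.intervals):
            for key in list(d):
                d[key] = resolve(d[key])
        if self.ad_genes:
            self.ad_genes = resolve(self.ad_genes)
        if self.network_genes:
            self.network_genes = resolve(self.network_genes)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    min_regions = int(p.get("min_regions", 3))
    window = tuple(p.get("window", (-2000, 2000)))
    alpha = float(p.get("alpha", 0.01))
    k = int(p.get("k", 200))
    min_size = int(p.get("min_size", 30))
    cut_height = float(p.get("cut_height", 0.75))
    n_iter = int(p.get("n_iter", 1000))
    coverage = float(p.get("coverage", 0.95))
    calibrate = bool(p.get("calibrate", True))
    mode = p.get("mode", "paper")

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "universe_n": config.universe_n,
        "parameters": {
            "min_regions": min_regions,
            "window": list(window),
            "alpha": alpha,
            "k": k,
            "min_size": min_size,
            "cut_height": cut_height,
            "n_iter": n_iter,
            "coverage": coverage,
            "calibrate": calibrate,
            "mode": mode,
        },
        "inputs": {},
        "stages": [],
    }

    # ---- load inputs -----------------------------------------------------
    region_names = sorted(config.regions)
    expr, meth, pheno = {}, {}, {}
    for region in region_names:
        paths = config.regions[region]
        pheno[region] = read_phenotype(paths["phenotype"])
        manifest["inputs"][f"{region}/phenotype"] = _sha256(paths["phenotype"])
        if "expression" in paths:
            expr[region] = read_matrix(paths["expression"], kind="expression")
            manifest["inputs"][f"{region}/expression"] = _sha256(paths["expression"])
        if "methylation" in paths:
            meth[region] = read_matrix(paths["methylation"], kind="methylation")
            manifest["inputs"][f"{region}/methylation"] = _sha256(paths["methylation"])
    for key, path in {**config.annotations, **config.intervals}.items():
        manifest["inputs"][key] = _sha256(path)

    # ---- screen ----------------------------------------------------------
    expr_corr = {r: spearman_age_correlation(expr[r], pheno[r], region=r) for r in expr}
    meth_corr = {r: spearman_age_correlation(meth[r], pheno[r], region=r) for r in meth}
    for r, t in {**expr_corr, **{f"{x}_meth": y for x, y in meth_corr.items()}}.items():
        _write_tsv(t.table.reset_index(), out / f"corr_{r}.tsv")
    manifest["stages"].append("screen")

    # ---- calibrate -------------------------------------------------------
    if calibrate:
        cals = {}
        for i, r in enumerate(sorted(expr)):
            cals[r] = calibrate_cutoff(
                expr[r], pheno[r], n_iter=n_iter, coverage=coverage,
                seed=int(config.seed) + i,
            )
        cutoff = max(c.cutoff_c for c in cals.values())
        (out / "calibration.json").write_text(
            json.dumps(
                {
                    r: {
                        "cutoff_c": c.cutoff_c,
                        "z_mean": c.z_mean,
                        "z_sd": c.z_sd,
                        "p_cutoff": c.p_cutoff,
                        "n_iter": c.n_iter,
                        "coverage": c.coverage,
                    }
                    for r, c in sorted(cals.items())
                }
                | {"pipeline_cutoff": cutoff},
                indent=1,
                sort_keys=True,
            )
        )
    else:
        cutoff = float(p.get("cutoff", DEFAULT_CUTOFF))
    manifest["parameters"]["cutoff"] = cutoff
    manifest["stages"].append("calibrate")

    # ---- consensus -------------------------------------------------------
    expr_cons = consensus_across_regions(
        [expr_corr[r] for r in sorted(expr_corr)], cutoff, min_regions=min_regions
    )
    meth_cons = consensus_across_regions(
        [meth_corr[r] for r in sorted(meth_corr)], cutoff, min_regions=min_regions
    ) if meth_corr else None
    _write_tsv(expr_cons.table.reset_index(), out / "consensus_expression.tsv")
    if meth_cons is not None:
        _write_tsv(meth_cons.table.reset_index(), out / "consensus_methylation.tsv")
    manifest["stages"].append("consensus")

    # ---- map sites -------------------------------------------------------
    meth_genes: set[str] = set()
    if meth_cons is not None and "sites" in config.intervals and "tss" in config.intervals:
        sites = read_bed(config.intervals["sites"])
        tss = read_bed(config.intervals["tss"])
        meth_genes, n_skipped = map_sites_to_genes(
            meth_cons.features, sites, tss, window=window
        )
        (out / "methylation_genes.txt").write_text(
            "\n".join(sorted(meth_genes)) + ("\n" if meth_genes else "")
        )
    manifest["stages"].append("map_sites")

    # ---- union -----------------------------------------------------------
    union = union_aging_genes(expr_cons.features, meth_genes)
    (out / "aging_genes.txt").write_text(
        "\n".join(sorted(union.union)) + ("\n" if union.union else "")
    )
    manifest["union"] = {
        "n_expression": len(expr_cons.features),
        "n_methylation_genes": len(meth_genes),
        "n_union": len(union.union),
        "n_intersection": len(union.intersection),
        "pct_of_expression": union.pct_of_expression,
    }
    manifest["stages"].append("union")

    # ---- TF prediction ---------------------------------------------------
    if "motif" in config.annotations:
        motif = read_gmt(config.annotations["motif"])
        per_region = {}
        for r in sorted(expr_corr):
            pos = sorted(
                set(expr_corr[r].scored().index[expr_corr[r].scored()["r"] > cutoff])
            )
            if not pos:
                continue
            top = rank_and_select_top(pos, expr_corr[r], limit=k)
            per_region[r] = predict_tfs_per_region(
                top, motif, config.universe_n, alpha=alpha, mode=mode
            )
            _write_tsv(per_region[r], out / f"tf_enrichment_{r}.tsv")
        tfs = tf_consensus(per_region, min_regions=min(min_regions, len(per_region)))
        coverage_rows = []
        all_input = sorted(expr_cons.positive)
        for tf in tfs:
            if all_input:
                frac, ok = target_coverage_filter(tf, all_input, motif)
            else:
                frac, ok = 0.0, False
            coverage_rows.append((tf, frac, ok))
        prof = tf_age_profile_check(
            tfs, [expr_corr[r] for r in sorted(expr_corr)], cutoff=cutoff,
            min_regions=min_regions,
        )
        _write_tsv(
            pd.DataFrame(coverage_rows, columns=["tf", "coverage_fraction", "pass"]),
            out / "tf_coverage.tsv",
        )
        _write_tsv(prof, out / "tf_age_profiles.tsv")
        manifest["tf_consensus"] = tfs
    manifest["stages"].append("tf_predict")

    # ---- modules ---------------------------------------------------------
    module_region = p.get("module_region", sorted(expr)[0] if expr else None)
    if module_region and expr_cons.features:
        mat = expr[module_region]
        genes = sorted(expr_cons.features & set(mat.feature_ids))
        if len(genes) >= 2:
            dist, kept = correlation_distance(mat, genes)
            assignment = detect_modules(
                dist, kept, min_size=min_size, cut_height=cut_height
            )
            _write_tsv(
                pd.DataFrame(
                    sorted(assignment.labels.items()), columns=["gene", "module"]
                ),
                out / "modules.tsv",
            )
            if "go" in config.annotations and assignment.n_modules:
                go = read_gmt(config.annotations["go"])
                _write_tsv(
                    module_enrichment(assignment, go, config.universe_n, alpha=alpha, mode=mode),
                    out / "module_enrichment.tsv",
                )
            manifest["n_modules"] = assignment.n_modules
    manifest["stages"].append("modules")

    # ---- network ---------------------------------------------------------
    if "motif" in config.annotations and "literature" in config.annotations:
        motif = read_gmt(config.annotations["motif"])
        lit = read_gmt(config.annotations["literature"])
        if config.network_genes:
            net_genes = read_gene_list(config.network_genes)
        else:
            net_genes = sorted(expr_cons.features)[: min(len(expr_cons.features), 200)]
        region0 = sorted(expr)[0]
        net_genes = [g for g in net_genes if g in set(expr[region0].feature_ids)]
        if net_genes:
            net = build_network(
                net_genes, expr[region0], motif, lit, config.universe_n,
                alpha=alpha, k=k, mode=mode,
            )
            _write_tsv(net.edges, out / "network_edges.tsv")
            (out / "network_summary.json").write_text(
                json.dumps(net.summary, indent=1, sort_keys=True)
            )
            manifest["network"] = net.summary
    manifest["stages"].append("network")

    # ---- disease overlap -------------------------------------------------
    if config.ad_genes:
        ad = read_gene_list(config.ad_genes)
        rep = gene_set_overlap(union.union, ad, config.universe_n)
        overlap_out = {
            "n_aging": rep.n_a,
            "n_disease": rep.n_b,
            "n_overlap": rep.n_overlap,
            "p_value": rep.p_value,
        }
        if "pathways" in config.annotations:
            pw = read_gmt(config.annotations["pathways"])
            sp = shared_pathways(union.union, ad, pw, config.universe_n, alpha=alpha)
            _write_tsv(sp.table, out / "shared_pathways.tsv")
            overlap_out["n_shared_pathways"] = len(sp.shared)
        (out / "overlap.json").write_text(json.dumps(overlap_out, indent=1, sort_keys=True))
        manifest["overlap"] = overlap_out
    manifest["stages"].append("overlap")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
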