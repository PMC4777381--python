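"""Synthetic multi-region cohorts with planted aging signal.

The generator emulates the structure of multi-region brain cohorts profiled
for expression and DNA methylation across a long lifespan:

* donor ages drawn uniformly over a wide range (default 15-101 years), one
  independent cohort per region (default 4 regions, 147 donors each);
* a fraction of features with a planted monotone age effect — each planted
  feature is a monotone function of the age *rank* (normal scores) plus
  Gaussian noise, so the target Spearman correlation ``effect_r`` is
  directly meaningful; the noise scale for a requested ``effect_r`` is
  solved by Monte-Carlo (no closed form for Spearman under this model);
* a shared core of planted features common to all regions plus
  region-private ones (``shared_fraction``), mimicking partial cross-region
  overlap;
* TF-driven co-expression blocks: each simulated TF gets a block of targets
  equal to the TF profile plus noise, inducing within-block correlation
  (default ~0.9);
* methylation matrices built by squashing the same latent planted profiles
  through a logistic link, giving beta values in (0, 1) while preserving
  the planted Spearman structure exactly (monotone transform);
* annotation collections (TF motif/literature targets, GO-like terms,
  pathways, a GenAge-like reference list, an AD-like list) consistent with
  the planted truth, plus a toy genome (TSS and site positions, ChIP
  sites) for the interval-based stages.

Everything is a pure function of the seeded configuration.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import expit

from .errors import ConfigError
from .io import (
    FeatureMatrix,
    GeneSet,
    GeneSetCollection,
    IntervalTable,
    Phenotype,
)
import pandas as pd

REGION_NAMES = ("CRBLM", "FCTX", "PONS", "TCTX")


def _stable_hash(label: str) -> int:
    """Process-independent 31-bit hash for seed derivation."""
    return zlib.crc32(label.encode()) % (2**31)


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic multi-region cohort."""

    seed: int
    n_samples: int = 147
    n_regions: int = 4
    age_range: tuple[float, float] = (15.0, 101.0)
    n_genes: int = 2000
    n_sites: int = 1000
    fraction_aging: float = 0.1
    effect_r: float = 0.6
    shared_fraction: float = 0.8
    n_tfs: int = 3
    targets_per_tf: int = 50
    block_within_r: float = 0.9
    #: TFs age-correlated (like the regulators the screen is meant to find)
    #: vs. independent block drivers (mutually uncorrelated target blocks)
    tf_age_effect: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_samples < 10:
            raise ConfigError("n_samples must be >= 10")
        for name in ("fraction_aging", "shared_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0 < self.effect_r < 1:
            raise ConfigError("effect_r must be in (0, 1)")
        if not 0 < self.block_within_r < 1:
            raise ConfigError("block_within_r must be in (0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must be increasing")
        if self.n_tfs * self.targets_per_tf > self.n_genes:
            raise ConfigError("TF target blocks exceed the gene count")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")

    @property
    def regions(self) -> list[str]:
        if self.n_regions <= len(REGION_NAMES):
            return list(REGION_NAMES[: self.n_regions])
        return [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def gene_ids(self) -> list[str]:
        tfs = [f"TF{i + 1}" for i in range(self.n_tfs)]
        rest = [f"G{i + 1:05d}" for i in range(self.n_genes - self.n_tfs)]
        return tfs + rest

    @property
    def site_ids(self) -> list[str]:
        return [f"cg{i + 1:06d}" for i in range(self.n_sites)]


@dataclass
class GroundTruth:
    """Planted truth used as the oracle by tests and the acceptance script."""

    positives: dict[str, set[str]] = field(default_factory=dict)  # region -> ids
    negatives: dict[str, set[str]] = field(default_factory=dict)
    shared_positives: set[str] = field(default_factory=set)
    shared_negatives: set[str] = field(default_factory=set)
    tf_targets: dict[str, set[str]] = field(default_factory=dict)
    modules: dict[str, int] = field(default_factory=dict)  # gene -> block index

    def __post_init__(self) -> None:
        for region in self.positives:
            if self.positives[region] & self.negatives.get(region, set()):
                raise ValueError("positive and negative truth sets overlap")

    @property
    def shared(self) -> set[str]:
        return self.shared_positives | self.shared_negatives

    def planted_anywhere(self) -> set[str]:
        out = set()
        for s in self.positives.values():
            out |= s
        for s in self.negatives.values():
            out |= s
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "positives": {k: sorted(v) for k, v in self.positives.items()},
            "negatives": {k: sorted(v) for k, v in self.negatives.items()},
            "shared_positives": sorted(self.shared_positives),
            "shared_negatives": sorted(self.shared_negatives),
            "tf_targets": {k: sorted(v) for k, v in self.tf_targets.items()},
            "modules": self.modules,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            positives={k: set(v) for k, v in d["positives"].items()},
            negatives={k: set(v) for k, v in d["negatives"].items()},
            shared_positives=set(d["shared_positives"]),
            shared_negatives=set(d["shared_negatives"]),
            tf_targets={k: set(v) for k, v in d["tf_targets"].items()},
            modules={k: int(v) for k, v in d["modules"].items()},
        )


# ---------------------------------------------------------------------------
# noise calibration


_NOISE_CACHE: dict[tuple[float, int], float] = {}


def _mean_abs_spearman(sigma: float, n: int, rng: np.random.Generator, reps: int = 400) -> float:
    z = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    x = z[None, :] + sigma * rng.standard_normal((reps, n))
    rx = stats.rankdata(x, axis=1)
    rz = stats.rankdata(z)
    sx = rx - rx.mean(axis=1, keepdims=True)
    sz = rz - rz.mean()
    num = sx @ sz
    den = np.sqrt((sx * sx).sum(axis=1) * (sz * sz).sum())
    return float(np.mean(np.abs(num / den)))


def noise_sd_for_effect(effect_r: float, n: int, tol: float = 0.02) -> float:
    """Noise standard deviation giving E|Spearman r| ~ effect_r for the
    monotone-in-age-rank effect model, solved by Monte-Carlo bisection.

    The Gaussian-copula closed form (sigma = sqrt(1/rho^2 - 1) with
    rho = 2 sin(pi * r_s / 6)) seeds the bracket; the result is cached per
    (effect_r, n) and deterministic.
    """
    key = (round(float(effect_r), 6), int(n))
    if key in _NOISE_CACHE:
        return _NOISE_CACHE[key]
    rho = 2.0 * np.sin(np.pi * effect_r / 6.0)
    sigma0 = float(np.sqrt(max(1.0 / rho**2 - 1.0, 1e-12)))
    lo, hi = sigma0 / 4.0, sigma0 * 4.0
    rng = np.random.default_rng(_stable_hash(repr(key)))
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        est = _mean_abs_spearman(mid, n, rng)
        if abs(est - effect_r) <= tol / 2:
            break
        if est > effect_r:  # too little noise
            lo = mid
        else:
            hi = mid
    _NOISE_CACHE[key] = mid
    return mid


# ---------------------------------------------------------------------------
# cohort and matrices


def _region_rngs(config: SimulationConfig, label: str) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence([config.seed, _stable_hash(label)])
    children = root.spawn(config.n_regions)
    return {r: np.random.default_rng(s) for r, s in zip(config.regions, children)}


def simulate_cohort(config: SimulationConfig) -> dict[str, Phenotype]:
    """One phenotype table per region; ages uniform on ``age_range``."""
    lo, hi = config.age_range
    out = {}
    for region, rng in _region_rngs(config, "cohort").items():
        ages = rng.uniform(lo, hi, size=config.n_samples)
        ids = [f"{region}_S{i + 1:04d}" for i in range(config.n_samples)]
        out[region] = Phenotype(ids, ages)
    return out


def _plant_assignments(config: SimulationConfig, ids: list[str], rng: np.random.Generator):
    """Split a feature namespace into shared/private planted sets per region."""
    n_planted = int(round(config.fraction_aging * len(ids)))
    order = list(rng.permutation(ids))
    planted = order[:n_planted]
    n_shared = int(round(config.shared_fraction * n_planted))
    shared = planted[:n_shared]
    private_pool = planted[n_shared:]
    half = len(shared) // 2
    shared_pos, shared_neg = set(shared[:half + len(shared) % 2]), set(shared[half + len(shared) % 2:])
    per_region_private: dict[str, list[str]] = {r: [] for r in config.regions}
    for i, f in enumerate(private_pool):
        per_region_private[config.regions[i % config.n_regions]].append(f)
    return shared_pos, shared_neg, per_region_private


def _age_scores(ages: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(ages)
    return stats.norm.ppf((ranks - 0.5) / ranks.size)


def _latent_profiles(
    config: SimulationConfig,
    phenotypes: dict[str, Phenotype],
    ids: list[str],
    seed_label: str,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Latent (pre-link) profiles per region plus the planted truth.

    TF features (ids starting with 'TF') always get a positive age effect;
    their target blocks are TF profile + block noise.
    """
    assign_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash(seed_label + "/assign")])
    )
    tf_ids = [i for i in ids if i.startswith("TF")]
    target_pool = [i for i in ids if not i.startswith("TF")]
    tf_targets: dict[str, set[str]] = {}
    modules: dict[str, int] = {}
    cursor = 0
    for b, tf in enumerate(tf_ids, start=1):
        block = target_pool[cursor : cursor + config.targets_per_tf]
        cursor += config.targets_per_tf
        tf_targets[tf] = set(block)
        modules[tf] = b
        for g in block:
            modules[g] = b
    plantable = [i for i in target_pool[cursor:]]
    shared_pos, shared_neg, private = _plant_assignments(
        config, plantable, assign_rng
    )

    truth = GroundTruth(
        shared_positives=shared_pos,
        shared_negatives=shared_neg,
        tf_targets=tf_targets,
        modules=modules,
    )

    sigma = noise_sd_for_effect(config.effect_r, config.n_samples)
    # block noise: corr(t1, t2) = var(tf) / (var(tf) + sd_t^2) = within_r
    var_tf = 1.0 + sigma**2
    sd_block = float(np.sqrt(var_tf * (1.0 - config.block_within_r) / config.block_within_r))

    profiles: dict[str, np.ndarray] = {}
    region_rngs = _region_rngs(config, seed_label + "/noise")
    for region in config.regions:
        rng = region_rngs[region]
        z = _age_scores(phenotypes[region].age)
        n = z.size
        half_priv = len(private[region]) // 2
        priv_pos = set(private[region][:half_priv])
        priv_neg = set(private[region][half_priv:])
        truth.positives[region] = set(shared_pos) | priv_pos
        truth.negatives[region] = set(shared_neg) | priv_neg

        idx_of = {f: i for i, f in enumerate(ids)}
        mat = np.empty((len(ids), n))
        tf_rows: dict[str, np.ndarray] = {}
        for i, f in enumerate(ids):
            if f.startswith("TF"):
                base = z if config.tf_age_effect else rng.standard_normal(n)
                row = base + sigma * rng.standard_normal(n)
                tf_rows[f] = row
            elif f in truth.positives[region]:
                row = z + sigma * rng.standard_normal(n)
            elif f in truth.negatives[region]:
                row = -z + sigma * rng.standard_normal(n)
            else:
                row = rng.standard_normal(n)
            mat[i] = row
        for tf, block in tf_targets.items():
            for g in block:
                mat[idx_of[g]] = tf_rows[tf] + sd_block * rng.standard_normal(n)
        profiles[region] = mat
    return profiles, truth


def simulate_expression(
    config: SimulationConfig, phenotypes: dict[str, Phenotype] | None = None
) -> tuple[dict[str, FeatureMatrix], GroundTruth]:
    """Expression matrices per region with planted age effects and TF blocks."""
    if phenotypes is None:
        phenotypes = simulate_cohort(config)
    ids = config.gene_ids
    profiles, truth = _latent_profiles(config, phenotypes, ids, "expression")
    out = {}
    for region, mat in profiles.items():
        df = pd.DataFrame(mat, index=ids, columns=phenotypes[region].sample_ids)
        out[region] = FeatureMatrix(df, kind="expression")
    return out, truth


def simulate_methylation(
    config: SimulationConfig, phenotypes: dict[str, Phenotype] | None = None
) -> tuple[dict[str, FeatureMatrix], GroundTruth]:
    """Methylation beta-value matrices per region.

    The latent planted profiles are passed through a logistic link with a
    per-site baseline offset, yielding beta values in (0, 1).  The link is
    strictly monotone, so the planted Spearman structure (and effect_r
    calibration) carries over exactly.
    """
    if phenotypes is None:
        phenotypes = simulate_cohort(config)
    site_cfg_ids = config.site_ids
    cfg = SimulationConfig(**{**asdict(config), "n_tfs": 0, "targets_per_tf": 0})
    profiles, truth = _latent_profiles(
        cfg, phenotypes, site_cfg_ids, "methylation"
    )
    base_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash("methylation/baseline")])
    )
    offsets = base_rng.normal(0.0, 1.0, size=len(site_cfg_ids))
    out = {}
    for region, mat in profiles.items():
        beta = expit(mat + offsets[:, None])
        df = pd.DataFrame(beta, index=site_cfg_ids, columns=phenotypes[region].sample_ids)
        out[region] = FeatureMatrix(df, kind="methylation")
    return out, truth


# ---------------------------------------------------------------------------
# annotations and toy genome


def simulate_annotations(
    config: SimulationConfig,
    truth: GroundTruth,
    padding: int = 0,
    genage_overlap: float = 0.5,
    genage_size: int = 60,
    n_go_terms: int = 10,
    go_size: int = 40,
    n_pathways: int = 8,
    pathway_size: int = 40,
    ad_shared_pathways: int = 3,
    ad_extra: int = 40,
) -> dict[str, GeneSetCollection]:
    """Annotation collections consistent with the planted truth.

    * ``motif`` / ``literature``: each TF's set is its true target block plus
      ``padding`` false-positive genes drawn from outside the block;
    * ``go``: GO-like term sets — one per planted module/pathway plus random
      filler terms;
    * ``pathways``: pathway sets built over the planted aging genes (each
      planted gene joins exactly one pathway) plus random filler;
    * ``genage``: a reference aging list overlapping the planted truth at
      ``genage_overlap``;
    * ``ad``: sets 'AD_DE' and 'AD_LIT' — each the union of
      ``ad_shared_pathways`` pathway cores plus non-aging filler genes, so
      exactly those pathways are enriched on both sides at padding=0.
    """
    if not 0 <= genage_overlap <= 1:
        raise ConfigError("genage_overlap must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash("annotations")])
    )
    ids = config.gene_ids
    planted = sorted(truth.shared)
    in_blocks = set().union(*truth.tf_targets.values()) if truth.tf_targets else set()
    null_genes = sorted(set(ids) - set(planted) - in_blocks - set(truth.tf_targets))

    def tf_collection() -> GeneSetCollection:
        sets = {}
        for tf in sorted(truth.tf_targets):
            members = sorted(truth.tf_targets[tf])
            if padding:
                pool = [g for g in null_genes if g not in members]
                pad = list(rng.choice(pool, size=min(padding, len(pool)), replace=False))
                members = members + sorted(pad)
            sets[tf] = GeneSet(f"targets of {tf}", tuple(members))
        return GeneSetCollection(sets)

    motif = tf_collection()
    literature = tf_collection()

    # pathways partition the planted aging genes
    pathways: dict[str, GeneSet] = {}
    chunks = [planted[i::n_pathways] for i in range(n_pathways)] if planted else []
    for i in range(n_pathways):
        core = chunks[i] if i < len(chunks) else []
        filler_pool = [g for g in null_genes]
        need = max(pathway_size - len(core), 0)
        filler = list(rng.choice(filler_pool, size=min(need, len(filler_pool)), replace=False))
        members = tuple(sorted(core) + sorted(filler))
        if members:
            pathways[f"PW{i + 1:02d}"] = GeneSet(f"pathway {i + 1}", members)
    pathway_coll = GeneSetCollection(pathways)

    # GO-like terms: planted modules (TF blocks) plus random filler terms
    go_sets: dict[str, GeneSet] = {}
    for b, tf in enumerate(sorted(truth.tf_targets), start=1):
        go_sets[f"GO_BLOCK{b}"] = GeneSet(
            f"block {b} program", tuple(sorted(truth.tf_targets[tf]))
        )
    for i in range(n_go_terms):
        members = tuple(
            sorted(rng.choice(ids, size=min(go_size, len(ids)), replace=False))
        )
        go_sets[f"GO_RAND{i + 1:02d}"] = GeneSet(f"random term {i + 1}", members)
    go_coll = GeneSetCollection(go_sets)

    # GenAge-like reference list
    n_from_truth = int(round(genage_overlap * genage_size))
    n_from_truth = min(n_from_truth, len(planted))
    from_truth = list(rng.choice(planted, size=n_from_truth, replace=False)) if n_from_truth else []
    n_fill = genage_size - n_from_truth
    fill = list(rng.choice(null_genes, size=min(n_fill, len(null_genes)), replace=False))
    genage = GeneSetCollection(
        {"GENAGE": GeneSet("reference aging genes", tuple(sorted(from_truth + fill)))}
    )

    # AD lists share exactly `ad_shared_pathways` pathway cores with the truth
    shared_ids = sorted(pathways)[: min(ad_shared_pathways, len(pathways))]
    ad_core: list[str] = []
    for pid in shared_ids:
        core = [g for g in pathway_coll.members(pid)]
        ad_core.extend(core[: max(len(core) // 2, 1)])
    remaining_null = [g for g in null_genes if g not in set(ad_core)]
    extra = list(rng.choice(remaining_null, size=min(ad_extra, len(remaining_null)), replace=False))
    ad_members = tuple(sorted(set(ad_core + extra)))
    ad = GeneSetCollection(
        {
            "AD_DE": GeneSet("AD differential-expression-like list", ad_members),
            "AD_LIT": GeneSet("AD literature-like list", ad_members),
        }
    )
    return {
        "motif": motif,
        "literature": literature,
        "go": go_coll,
        "pathways": pathway_coll,
        "genage": genage,
        "ad": ad,
    }


def simulate_genome(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    meth_truth: GroundTruth | None = None,
    gene_spacing: int = 10_000,
    chip_tf: str | None = None,
) -> dict[str, IntervalTable]:
    """A toy genome: one TSS per gene on chr1 (alternating strands), each
    methylation site placed inside the promoter of its host gene (site i is
    hosted by gene i mod n_genes), and ChIP sites for ``chip_tf`` (default:
    first TF) in the promoters of its true targets."""
    genes = config.gene_ids
    tss_rows = []
    pos = 100_000
    tss_of: dict[str, tuple[int, str]] = {}
    for i, g in enumerate(genes):
        strand = "+" if i % 2 == 0 else "-"
        tss_rows.append(("chr1", pos, pos + 1, g, strand))
        tss_of[g] = (pos, strand)
        pos += gene_spacing
    tss = IntervalTable(
        pd.DataFrame(tss_rows, columns=["chrom", "start", "end", "name", "strand"])
    )

    site_rows = []
    for j, site in enumerate(config.site_ids):
        host = genes[j % len(genes)]
        t, strand = tss_of[host]
        offset = 200 + 37 * (j % 40)  # within +-2000 of the TSS
        p = t + offset if strand == "+" else t - offset
        site_rows.append(("chr1", p, p + 2, site, "."))
    sites = IntervalTable(
        pd.DataFrame(site_rows, columns=["chrom", "start", "end", "name", "strand"])
    )

    chip_rows = []
    if truth is not None and truth.tf_targets:
        tf = chip_tf or sorted(truth.tf_targets)[0]
        for g in sorted(truth.tf_targets[tf]):
            t, strand = tss_of[g]
            p = t + 500 if strand == "+" else t - 500
            chip_rows.append(("chr1", p, p + 10, f"{tf}_site_{g}", "."))
    chip = IntervalTable(
        pd.DataFrame(
            chip_rows, columns=["chrom", "start", "end", "name", "strand"]
        )
        if chip_rows
        else pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
    ) if chip_rows else None

    out = {"tss": tss, "sites": sites}
    if chip is not None:
        out["chip"] = chip
    return out
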