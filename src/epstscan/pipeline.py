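"""End-to-end driver chaining every analysis stage.

Stage order mirrors the analysis narrative: preprocessing (array QC,
feature filtering, quantile normalization, KNN imputation), the three RDA
models with RDA2 contribution tails and Ward clustering, the per-transcript
two-way ANOVA, the per-sex additivity-filtered eP_ST permutation scan, the
cross-analysis candidate intersection, and the phenotype statistics.  Every
intermediate table is written as TSV with a provenance header carrying the
manifest hash; identical configuration and seed give identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import diffexpr, epst, io, ordination, phenotypes, preprocess
from .simulate import SimConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of real input paths or a SimConfig.

    Stage parameters carry the analysis defaults: 3% array non-uniformity
    cap, k=10 imputation neighbours, BH cutoff 1e-4, additivity alpha 0.01,
    5000 permutations, 0.999 outlier quantile.
    """

    out_dir: str = "results"
    expression_path: str | None = None
    expression_format: str = "tsv"
    metadata_path: str | None = None
    flags_path: str | None = None
    phenotype_path: str | None = None
    sim: SimConfig | None = None

    max_nonuniform_frac: float = 0.03
    impute_k: int = 10
    anova_cutoff: float = 1e-4
    alpha_add: float = 0.01
    n_perm: int = 5000
    outlier_q: float = 0.999
    tail_lower_q: float = 0.001
    tail_upper_q: float = 0.999
    n_clusters: int = 2
    seed: int = 0

    def validate(self) -> None:
        has_paths = self.expression_path is not None
        has_sim = self.sim is not None
        if has_paths == has_sim:
            raise ValueError("exactly one of expression_path or sim must be given")
        if has_paths and self.metadata_path is None:
            raise ValueError("metadata_path is required with real inputs")
        if not (0 < self.max_nonuniform_frac < 1):
            raise ValueError("max_nonuniform_frac must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.outlier_q < 1):
            raise ValueError("outlier_q must lie in (0, 1)")
        if not (0 < self.tail_lower_q < 1 and 0 < self.tail_upper_q < 1):
            raise ValueError("tail quantiles must lie in (0, 1)")

    def manifest(self) -> dict:
        # out_dir is excluded: bundle content must not depend on where it lands
        d = {
            k: v for k, v in dataclasses.asdict(self).items()
            if k not in ("sim", "out_dir")
        }
        d["sim"] = dataclasses.asdict(self.sim) if self.sim else None
        d["version"] = __version__
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        ds = generate_dataset(config.sim)
        return ds.expression, ds.metadata, ds.flags, ds.phenotypes, ds.truth
    matrix = io.read_expression(config.expression_path, format=config.expression_format)
    metadata = io.read_metadata(config.metadata_path, expression=matrix)
    if config.flags_path:
        flags = io.read_flags(config.flags_path, matrix)
    else:
        flags = preprocess.FeatureFlags(
            uniform=pd.DataFrame(True, index=matrix.index, columns=matrix.columns),
            negative_filtered=pd.DataFrame(False, index=matrix.index, columns=matrix.columns),
        )
    pheno = io.read_phenotypes(config.phenotype_path) if config.phenotype_path else None
    return matrix, metadata, flags, pheno, None


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle to ``config.out_dir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = config.manifest()
    results: dict = {"manifest": manifest}

    matrix, metadata, flags, pheno, truth = _load_inputs(config)
    if truth is not None:
        io.write_table(truth, out / "truth.tsv", manifest)

    # --- preprocess -------------------------------------------------------
    matrix = preprocess.qc_filter_arrays(matrix, flags, config.max_nonuniform_frac)
    matrix = preprocess.filter_features(matrix, flags)
    matrix = preprocess.quantile_normalize(matrix)
    matrix = preprocess.impute_missing(matrix, k=config.impute_k)
    metadata = metadata.loc[[s for s in matrix.columns if s in set(metadata.index)]]
    io.write_expression(matrix, out / "normalized.tsv",
                        header_comment=f"manifest_hash={io.manifest_hash(manifest)}")
    results["normalized"] = matrix

    # --- ordination -------------------------------------------------------
    Y = matrix.T.loc[metadata.index]
    partition = ordination.variance_partition(Y, metadata)
    results["variance_partition"] = partition
    part_tab = pd.DataFrame(
        {
            "model": ["Sex+Progeny", "Sex+Condition(Progeny)", "Progeny+Condition(Sex)"],
            "constrained_variance": [
                partition.full.axis_eigenvalues.sum(),
                partition.sex_partial.axis_eigenvalues.sum(),
                partition.progeny_partial.axis_eigenvalues.sum(),
            ],
            "fraction_of_explained": [
                1.0,
                partition.sex_fraction_of_explained,
                partition.progeny_fraction_of_explained,
            ],
        }
    )
    io.write_table(part_tab, out / "variance_partition.tsv", manifest, index=False)
    contributions = partition.full.transcript_contributions
    io.write_table(contributions, out / "rda_contributions.tsv", manifest)

    if contributions.shape[1] >= 2:
        rda2 = contributions.iloc[:, 1]
        tails = ordination.contribution_tails(
            rda2, lower_q=config.tail_lower_q, upper_q=config.tail_upper_q
        )
        clusters = ordination.cluster_transcripts(
            matrix.loc[tails], n_clusters=config.n_clusters
        )
        io.write_table(clusters.to_frame(), out / "rda2_tail_clusters.tsv", manifest)
    else:
        logger.warning("fewer than 2 constrained axes; skipping RDA2 tails")
        tails, clusters = [], pd.Series(dtype=int)
    results["rda2_tails"] = tails
    results["clusters"] = clusters

    # --- differential expression -----------------------------------------
    anova = diffexpr.two_way_anova(matrix, metadata)
    io.write_table(anova, out / "anova.tsv", manifest)
    de_progeny = diffexpr.select_by_threshold(anova, "progeny", config.anova_cutoff)
    de_sex = diffexpr.select_by_threshold(anova, "sex", config.anova_cutoff)
    (out / "de_progeny.txt").write_text("\n".join(map(str, de_progeny)) + "\n")
    results["anova"] = anova
    results["de_progeny"] = de_progeny
    results["de_sex"] = de_sex
    logger.info("ANOVA: %d sex-DE, %d progeny-DE at padj<%g",
                len(de_sex), len(de_progeny), config.anova_cutoff)

    # --- eP_ST scan per sex ----------------------------------------------
    scans = {}
    for i, sex in enumerate(("M", "F")):
        scan = epst.permutation_scan(
            matrix, metadata, sex=sex,
            alpha_add=config.alpha_add, n_perm=config.n_perm,
            outlier_q=config.outlier_q, seed=config.seed + i,
        )
        io.write_table(scan, out / f"epst_{sex}.tsv", manifest)
        scans[sex] = scan
    results["epst"] = scans

    outlier_lists = [
        scans[sex].index[scans[sex]["outlier"]].tolist() for sex in ("M", "F")
    ]
    common = epst.common_candidates(de_progeny, tails, *outlier_lists) \
        if tails else []
    (out / "common_candidates.txt").write_text("\n".join(map(str, common)) + "\n")
    results["common_candidates"] = common

    # --- phenotypes -------------------------------------------------------
    if pheno is not None:
        counts = phenotypes.sex_counts(pheno)
        ratio = phenotypes.sex_ratio_test(counts)
        ci = phenotypes.ci_anova(pheno)
        io.write_table(counts, out / "sex_counts.tsv", manifest)
        io.write_table(ratio.pairwise, out / "sex_ratio_tests.tsv", manifest, index=False)
        io.write_table(ci.anova, out / "ci_anova.tsv", manifest)
        letters = pd.DataFrame(
            {"progeny": list(ci.letters), "letters": list(ci.letters.values())}
        )
        io.write_table(letters, out / "ci_letters.tsv", manifest, index=False)
        results["sex_ratio"] = ratio
        results["ci_anova"] = ci

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    (out / "log.txt").write_text(
        f"manifest_hash={io.manifest_hash(manifest)}\n"
        f"samples={matrix.shape[1]} transcripts={matrix.shape[0]}\n"
        f"sex_de={len(de_sex)} progeny_de={len(de_progeny)}\n"
        f"additive_M={len(scans['M'])} additive_F={len(scans['F'])}\n"
        f"outliers_M={int(scans['M']['outlier'].sum()) if len(scans['M']) else 0} "
        f"outliers_F={int(scans['F']['outlier'].sum()) if len(scans['F']) else 0}\n"
        f"common_candidates={len(common)}\n"
    )
    return results
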