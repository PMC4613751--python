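"""Synthetic gonad-microarray datasets with the structure the pipeline assumes.

The generator emulates a three-progeny common-garden design: two parental
populations (FRA, DAN) and their hybrids (HYB), ~60 individuals per
progeny of both sexes, expression measured as log2 intensities on an array
of ~32k transcripts.  Structure injected:

* a dominant sex effect on a configurable fraction of transcripts,
* a smaller progeny effect (FRA mean = mu - delta, DAN mean = mu + delta),
* hybrids at the mid-parent mean for additively inherited transcripts and
  displaced by ``dominance_shift`` otherwise,
* i.i.d. Gaussian noise on the log2 scale,
* missing cells and quality-flagged features at configurable rates,
* a phenotype table with per-progeny sex-ratios and condition-index means.

A truth table of which transcripts are sex-DE / progeny-DE / additive is
returned alongside, so every downstream stage can be scored against the
planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import FeatureFlags

__all__ = ["SimConfig", "SimulatedDataset", "generate_dataset"]

# observed female fractions echo the study design: DAN female-biased,
# FRA male-biased, HYB intermediate
_DEFAULT_FEMALE_FRAC = {"DAN": 0.60, "FRA": 0.27, "HYB": 0.42}
_DEFAULT_CI_MEAN = {"DAN": 17.5, "FRA": 16.4, "HYB": 17.5}


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    All expression-scale parameters are in log2-intensity units.
    ``frac_additive`` is the fraction *of progeny-DE transcripts* whose
    hybrid mean sits exactly at the mid-parent value; the rest are shifted
    by ``dominance_shift``.  Transcripts not progeny-DE are additive by
    construction (all three progenies share the same mean).
    """

    n_transcripts: int = 31918
    n_per_progeny: int = 60
    sex_effect_sd: float = 1.0
    progeny_effect_sd: float = 0.5
    noise_sd: float = 0.5
    frac_sex_de: float = 0.36
    frac_progeny_de: float = 0.01
    frac_additive: float = 0.5
    dominance_shift: float = 0.75
    missing_rate: float = 0.01
    bad_feature_rate: float = 0.005
    seed: int = 0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    female_frac: dict = field(default_factory=lambda: dict(_DEFAULT_FEMALE_FRAC))
    ci_mean: dict = field(default_factory=lambda: dict(_DEFAULT_CI_MEAN))
    ci_sd: float = 1.0

    def validate(self) -> None:
        for name in ("n_transcripts", "n_per_progeny"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("sex_effect_sd", "progeny_effect_sd", "noise_sd",
                     "baseline_sd", "ci_sd"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("frac_sex_de", "frac_progeny_de", "frac_additive",
                     "missing_rate", "bad_feature_rate"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not np.isfinite(float(self.dominance_shift)):
            raise ValueError(f"dominance_shift must be finite, got {self.dominance_shift!r}")
        for progeny in ("FRA", "DAN", "HYB"):
            f = self.female_frac.get(progeny)
            if f is None or not (0.0 <= f <= 1.0):
                raise ValueError(f"female_frac[{progeny!r}] must lie in [0, 1], got {f!r}")
            if self.ci_mean.get(progeny) is None:
                raise ValueError(f"ci_mean[{progeny!r}] missing")


@dataclass
class SimulatedDataset:
    expression: pd.DataFrame       # transcripts x samples, NaN = missing
    metadata: pd.DataFrame         # sample_id index: progeny, sex, array_id
    flags: FeatureFlags
    phenotypes: pd.DataFrame
    truth: pd.DataFrame            # transcript_id index: sex_de, progeny_de, additive
    config: SimConfig

    def tables(self) -> dict:
        return {
            "expression": self.expression,
            "metadata": self.metadata,
            "phenotypes": self.phenotypes,
            "truth": self.truth,
        }


def _sample_metadata(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for progeny in ("FRA", "DAN", "HYB"):
        n = cfg.n_per_progeny
        n_female = int(round(cfg.female_frac[progeny] * n))
        sexes = ["F"] * n_female + ["M"] * (n - n_female)
        for i, sex in enumerate(sexes):
            rows.append(
                {
                    "sample_id": f"{progeny}_{i + 1:03d}",
                    "progeny": progeny,
                    "sex": sex,
                    "array_id": f"array_{len(rows) // 4 + 1:02d}",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw a full synthetic dataset from the configured generative model.

    Deterministic given ``config.seed``: the same configuration always
    yields byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _sample_metadata(config, rng)
    n_t, n_s = config.n_transcripts, len(meta)
    transcript_ids = pd.Index(
        [f"T{i + 1:06d}" for i in range(n_t)], name="transcript_id"
    )

    sex_de = rng.random(n_t) < config.frac_sex_de
    progeny_de = rng.random(n_t) < config.frac_progeny_de
    additive_among_de = rng.random(n_t) < config.frac_additive
    additive = ~progeny_de | additive_among_de  # non-DE transcripts are trivially additive

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_t)
    sex_effect = np.where(sex_de, rng.normal(0.0, config.sex_effect_sd, size=n_t), 0.0)
    delta = np.where(progeny_de, rng.normal(0.0, config.progeny_effect_sd, size=n_t), 0.0)

    is_female = (meta["sex"] == "F").to_numpy()
    progeny = meta["progeny"].to_numpy()
    mean = np.tile(baseline[:, None], (1, n_s))
    mean += np.where(is_female[None, :], sex_effect[:, None] / 2.0, -sex_effect[:, None] / 2.0)
    hyb_shift = np.where(progeny_de & ~additive, config.dominance_shift, 0.0)
    mean[:, progeny == "FRA"] += -delta[:, None]
    mean[:, progeny == "DAN"] += delta[:, None]
    mean[:, progeny == "HYB"] += hyb_shift[:, None]  # mid-parent is the baseline

    values = mean + rng.normal(0.0, config.noise_sd, size=(n_t, n_s))
    expression = pd.DataFrame(values, index=transcript_ids, columns=meta.index)

    nonuniform = rng.random((n_t, n_s)) < config.bad_feature_rate
    negative = rng.random((n_t, n_s)) < config.bad_feature_rate
    flags = FeatureFlags(
        uniform=pd.DataFrame(~nonuniform, index=transcript_ids, columns=meta.index),
        negative_filtered=pd.DataFrame(negative, index=transcript_ids, columns=meta.index),
    )
    missing = rng.random((n_t, n_s)) < config.missing_rate
    # keep every transcript observable somewhere
    all_gone = missing.all(axis=1)
    missing[all_gone, 0] = False
    expression = expression.mask(pd.DataFrame(missing, index=transcript_ids, columns=meta.index))

    ci = np.array([config.ci_mean[p] for p in progeny]) + rng.normal(0.0, config.ci_sd, size=n_s)
    ci = np.clip(ci, 0.1, 99.9)
    total_weight = np.clip(rng.normal(50.0, 8.0, size=n_s), 5.0, None)
    phenotypes = pd.DataFrame(
        {
            "progeny": progeny,
            "sex": meta["sex"].to_numpy(),
            "total_weight": total_weight,
            "wet_flesh_weight": total_weight * ci / 100.0,
            "condition_index": ci,
        },
        index=meta.index,
    )

    truth = pd.DataFrame(
        {"sex_de": sex_de, "progeny_de": progeny_de, "additive": additive},
        index=transcript_ids,
    )
    return SimulatedDataset(
        expression=expression,
        metadata=meta,
        flags=flags,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )
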