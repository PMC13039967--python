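"""Synthetic cohort and LC-MS feature-table generator.

Emulates a multi-study pediatric fatty-liver cohort with K latent metabotypes:
clinical variables drawn from per-cluster log-normal (right-skewed positives)
or normal (age, blood pressures) distributions whose locations default to the
published per-metabotype medians; histology scores from cluster-conditional
ordinal distributions; sparse clinical missingness; optional extreme (>5 SD)
subjects. Metabolomics tables carry two ionization modes, two instrument
sources, triplicate injections with configurable replicate CV, per-study batch
location/scale shifts, mass-accuracy (ppm) noise, pathway-structured planted
intensity effects, planted clinical-metabolite association blocks, and a
configurable fraction of multivariate outlier samples.

Everything is deterministic for a fixed seed, and every planted signal is
recorded in a :class:`GroundTruth` object so downstream recovery is testable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import PathwayReference, make_toy_pathway_reference
from .preprocess import FeatureTable

__all__ = [
    "SimConfig",
    "ModeConfig",
    "BatchShift",
    "GroundTruth",
    "generate_cohort",
    "generate_feature_tables",
    "make_toy_pathway_reference",
    "CLUSTER_NAMES",
]

CLUSTER_NAMES = ("early_mild", "cardiometabolic", "inflammatory_fibrotic")

# z value of the 75th percentile of the standard normal; converts an IQR to an
# SD (normal) or a log-SD (log-normal)
_Z75 = 0.6744897501960817

# Per-cluster (median, q1, q3) for continuous variables, in the cluster order
# early-mild, cardiometabolic, inflammatory-fibrotic. Locations follow the
# published per-metabotype medians; right-skewed positives are log-normal so
# the configured location is exactly the distribution median.
_CONTINUOUS: dict[str, tuple[str, list[tuple[float, float, float]]]] = {
    "age": ("normal", [(11, 9, 12), (15, 13, 16), (12, 11, 13)]),
    "alt": ("lognormal", [(77, 54, 111), (79, 56, 105), (256, 219, 300)]),
    "ast": ("lognormal", [(48, 35, 62), (45, 35, 60), (136, 117, 164)]),
    "wc": ("lognormal", [(96, 87, 104), (114, 104, 123), (106, 97, 113)]),
    "ldl": ("lognormal", [(87, 69, 107), (105, 91, 127), (105, 80, 130)]),
    "tg": ("lognormal", [(110, 77, 143), (170, 129, 228), (143, 111, 215)]),
    "homa2ir": ("lognormal", [(2.6, 1.8, 3.7), (4.4, 2.9, 6.3), (4.8, 2.8, 7.0)]),
    "uric_acid": ("lognormal", [(5.2, 4.5, 6.0), (6.8, 5.9, 7.7), (5.8, 4.9, 6.6)]),
    "sbp": ("normal", [(114, 107, 123), (127, 118, 135), (122, 112, 129)]),
    # profiling variables
    "bmi": ("lognormal", [(28.9, 26.0, 31.6), (35.2, 32.1, 39.0), (32.0, 28.3, 35.2)]),
    "bmi_z": ("normal", [(2.2, 1.9, 2.6), (2.4, 2.1, 2.7), (2.3, 2.0, 2.8)]),
    "hdl": ("lognormal", [(40, 34, 45), (36, 32, 42), (40, 33, 45)]),
    "tc": ("lognormal", [(149, 129, 173), (179, 159, 206), (182, 151, 210)]),
    "ggt": ("lognormal", [(31, 23, 45), (38, 27, 54), (65, 49, 106)]),
    "glucose": ("lognormal", [(87, 81, 94), (88, 81, 93), (88, 83, 97)]),
    "insulin": ("lognormal", [(21, 14, 30), (35, 23, 53), (39, 22, 58)]),
    "dbp": ("normal", [(65, 59, 70), (71, 65, 77), (69, 63, 74)]),
}

CLUSTERING_VARS = (
    "age", "alt", "ast", "wc", "vldl", "ldl", "tg", "homa2ir", "uric_acid", "sbp",
)

# Per-cluster level counts for categorical/ordinal variables (cohort frequency
# defaults), same cluster order as above.
_CATEGORICAL: dict[str, tuple[tuple, list[list[float]]]] = {
    "sex": (("male", "female"), [[174, 80], [147, 42], [56, 15]]),
    "ethnicity": (("hispanic", "non_hispanic"), [[206, 48], [116, 73], [58, 13]]),
    "study": (("DB1", "DB2", "TONIC"), [[11, 213, 30], [12, 130, 47], [0, 55, 16]]),
    "steatosis": ((0, 1, 2, 3), [[2, 69, 81, 102], [2, 57, 69, 61], [1, 24, 20, 26]]),
    "lobular_inflammation": ((0, 1, 2, 3), [[2, 170, 76, 6], [0, 124, 58, 7], [0, 25, 36, 10]]),
    "ballooning": ((0, 1, 2), [[185, 55, 14], [115, 53, 21], [18, 26, 27]]),
    "fibrosis_stage": ((0, 1, 2, 3, 4), [[83, 100, 29, 39, 3], [77, 66, 31, 13, 2], [9, 12, 25, 23, 2]]),
    "mash_category": (
        ("no", "borderline z1", "borderline z3", "definite"),
        [[84, 113, 23, 34], [72, 31, 39, 47], [3, 9, 15, 44]],
    ),
}


@dataclass
class ModeConfig:
    """Per-ionization-mode generation settings."""

    n_background_features: int = 400
    n_replicates: int = 3
    replicate_cv: float = 0.10
    ppm_noise_sd: float = 2.0  # mass-accuracy noise, ppm


@dataclass
class BatchShift:
    """Per-study location/scale shift applied on the log2 intensity scale."""

    location: float = 0.0
    scale: float = 1.0


@dataclass
class PlantedAssociation:
    """A clinical-metabolite association block confined to one cluster."""

    clinical_var: str
    cluster: int
    slope: float  # log2 units per SD of the clinical variable


def _default_modes() -> dict[str, ModeConfig]:
    # paper-scale merged feature counts; tests pass smaller explicit configs
    return {
        "hilic_pos": ModeConfig(n_background_features=3758),
        "c18_neg": ModeConfig(n_background_features=3520),
    }


def _default_studies() -> dict[str, BatchShift]:
    return {
        "DB1": BatchShift(0.25, 1.0),
        "DB2": BatchShift(0.0, 1.0),
        "TONIC": BatchShift(-0.25, 1.1),
    }


def _default_planted_pathways() -> dict[str, tuple[int, float]]:
    # pathway -> (affected cluster index, log2 effect); directions mirror the
    # cohort findings (tryptophan metabolites up in inflammatory-fibrotic,
    # purine metabolites up in cardiometabolic)
    return {
        "tryptophan metabolism": (2, 1.0),
        "purine metabolism": (1, 1.0),
    }


def _default_planted_associations() -> dict[str, PlantedAssociation]:
    return {
        "tryptophan metabolism": PlantedAssociation("alt", 2, 0.8),
    }


@dataclass
class SimConfig:
    """Full specification of one synthetic study.

    ``clinical_params`` maps variable -> (dist, [(median, q1, q3)] per cluster)
    for continuous variables; ``categorical_params`` maps variable ->
    (levels, per-cluster level weights). ``sources`` groups studies into
    instrument sources that are matched/merged downstream.
    """

    n_subjects: int = 514
    cluster_proportions: tuple[float, ...] = (254 / 514, 189 / 514, 71 / 514)
    clinical_params: dict = field(default_factory=lambda: dict(_CONTINUOUS))
    categorical_params: dict = field(default_factory=lambda: dict(_CATEGORICAL))
    missing_rate: float = 0.0034
    n_extreme_subjects: int = 0
    fixed_counts: bool = False
    correlation: np.ndarray | None = None  # within-cluster corr of clustering vars
    studies: dict[str, BatchShift] = field(default_factory=_default_studies)
    sources: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"orbi": ("DB1", "TONIC"), "hfqe": ("DB2",)}
    )
    modes: dict[str, ModeConfig] = field(default_factory=_default_modes)
    planted_pathways: dict[str, tuple[int, float]] = field(
        default_factory=_default_planted_pathways
    )
    planted_associations: dict[str, PlantedAssociation] = field(
        default_factory=_default_planted_associations
    )
    outlier_sample_rate: float = 24 / 514
    outlier_log2_sd: float = 4.0
    feature_base_mean: float = 17.0  # log2 abundance location
    feature_base_sd: float = 1.5
    subject_log2_sd: float = 0.7  # biological between-subject noise
    shared_background_fraction: float = 0.8  # background features present in both sources
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.cluster_proportions)

    def validate(self) -> None:
        props = np.asarray(self.cluster_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"cluster_proportions sum to {props.sum()}, not 1")
        if (props <= 0).any():
            raise ValueError("all cluster proportions must be positive")
        if self.k < 2:
            raise ValueError("need at least two clusters")
        if self.n_subjects < 10 * self.k:
            raise ValueError(f"n_subjects must be >= 10*K = {10 * self.k}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for mode, mc in self.modes.items():
            if mc.n_replicates < 1:
                raise ValueError(f"{mode}: replicate count must be >= 1")
            if mc.ppm_noise_sd < 0:
                raise ValueError(f"{mode}: ppm_noise_sd must be >= 0")
            if mc.replicate_cv < 0:
                raise ValueError(f"{mode}: replicate_cv must be >= 0")
        for name, shift in self.studies.items():
            if shift.scale <= 0:
                raise ValueError(f"study {name}: scale must be > 0")
        for var, (dist, rows) in self.clinical_params.items():
            if len(rows) != self.k:
                raise ValueError(f"{var}: expected {self.k} per-cluster parameter rows")
            for med, q1, q3 in rows:
                if dist == "lognormal" and med <= 0:
                    raise ValueError(f"{var}: log-normal location must be positive")
                if q3 < q1:
                    raise ValueError(f"{var}: q3 < q1")


@dataclass
class GroundTruth:
    """Recovery oracle: everything the generator planted.

    feature keys are "<mode>:<feature_id>"; ``subject_z`` stores the standard-
    normal draws behind each subject's clustering variables (used to plant
    within-cluster clinical-metabolite associations consistently).
    """

    subject_cluster: dict[str, int]
    subject_study: dict[str, str] = field(default_factory=dict)
    subject_z: pd.DataFrame | None = None
    feature_compound: dict[str, tuple[str, str, str | None]] = field(default_factory=dict)
    differential_features: set[str] = field(default_factory=set)
    outlier_subjects: set[str] = field(default_factory=set)
    extreme_subjects: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if len(set(self.subject_cluster)) != len(self.subject_cluster):
            raise ValueError("duplicate subjects in subject_cluster")

    def to_json(self, path) -> None:
        doc = {
            "subject_cluster": self.subject_cluster,
            "subject_study": self.subject_study,
            "feature_compound": {k: list(v) for k, v in self.feature_compound.items()},
            "differential_features": sorted(self.differential_features),
            "outlier_subjects": sorted(self.outlier_subjects),
            "extreme_subjects": sorted(self.extreme_subjects),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            subject_cluster=doc["subject_cluster"],
            subject_study=doc["subject_study"],
            feature_compound={
                k: (v[0], v[1], v[2]) for k, v in doc["feature_compound"].items()
            },
            differential_features=set(doc["differential_features"]),
            outlier_subjects=set(doc["outlier_subjects"]),
            extreme_subjects=set(doc["extreme_subjects"]),
        )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _transform(dist: str, med: float, q1: float, q3: float, z: np.ndarray) -> np.ndarray:
    if dist == "lognormal":
        sigma = math.log(q3 / q1) / (2 * _Z75) if q3 > q1 else 0.0
        return np.exp(math.log(med) + sigma * z)
    sd = (q3 - q1) / (2 * _Z75)
    return med + sd * z


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the clinical table and its ground truth.

    Cluster labels are i.i.d. categorical with the configured proportions
    (multinomial realized counts) unless ``fixed_counts`` is set. VLDL is
    emitted as TG/5 before rounding. Missingness and extreme subjects are
    injected after the clean table is drawn.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n, k = config.n_subjects, config.k
    props = np.asarray(config.cluster_proportions, dtype=float)

    if config.fixed_counts:
        counts = np.floor(props * n).astype(int)
        counts[: n - counts.sum()] += 1
        labels = np.repeat(np.arange(k), counts)
        rng.shuffle(labels)
    else:
        labels = rng.choice(k, size=n, p=props)

    subjects = [f"S{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame({"subject_id": subjects})

    sampled_clustering = [v for v in CLUSTERING_VARS if v != "vldl"]
    # standard-normal draws for the clustering variables, optionally correlated
    d = len(sampled_clustering)
    if config.correlation is not None:
        R = np.asarray(config.correlation, dtype=float)
        if R.shape != (d, d):
            raise ValueError(f"correlation must be {d}x{d} (clustering variables minus VLDL)")
        L = np.linalg.cholesky(R)
        Z = rng.standard_normal((n, d)) @ L.T
    else:
        Z = rng.standard_normal((n, d))
    zcols = {v: Z[:, j] for j, v in enumerate(sampled_clustering)}

    for var, (dist, rows) in config.clinical_params.items():
        z = zcols[var] if var in zcols else rng.standard_normal(n)
        vals = np.empty(n)
        for c in range(k):
            m = labels == c
            med, q1, q3 = rows[c]
            vals[m] = _transform(dist, med, q1, q3, z[m])
        df[var] = vals
    df["vldl"] = df["tg"] / 5.0

    for var, (levels, weights) in config.categorical_params.items():
        vals = np.empty(n, dtype=object)
        for c in range(k):
            m = labels == c
            w = np.asarray(weights[c], dtype=float)
            draw = rng.choice(len(levels), size=int(m.sum()), p=w / w.sum())
            vals[m] = [levels[i] for i in draw]
        df[var] = vals
    for ordinal in ("steatosis", "lobular_inflammation", "ballooning", "fibrosis_stage"):
        if ordinal in df:
            df[ordinal] = df[ordinal].astype(int)
    if {"steatosis", "lobular_inflammation", "ballooning"} <= set(df.columns):
        df["nas"] = df["steatosis"] + df["lobular_inflammation"] + df["ballooning"]

    numeric = [v for v in config.clinical_params] + ["vldl"]
    df[numeric] = df[numeric].round(2)

    truth = GroundTruth(
        subject_cluster=dict(zip(subjects, (int(c) for c in labels))),
        subject_study=dict(zip(subjects, df["study"])) if "study" in df else {},
        subject_z=pd.DataFrame(Z, index=subjects, columns=sampled_clustering),
    )

    # sparse missingness over the continuous clinical cells
    if config.missing_rate > 0:
        mask = rng.random((n, len(numeric))) < config.missing_rate
        block = df[numeric].to_numpy(float)
        block[mask] = np.nan
        df[numeric] = block

    # extreme subjects: one clustering variable pushed 6-8 SD from the mean
    if config.n_extreme_subjects > 0:
        chosen = rng.choice(n, size=config.n_extreme_subjects, replace=False)
        for i in chosen:
            var = CLUSTERING_VARS[rng.integers(len(CLUSTERING_VARS))]
            col = df[var].to_numpy(float)
            mu, sd = np.nanmean(col), np.nanstd(col, ddof=1)
            direction = 1 if rng.random() < 0.5 else -1
            value = mu + direction * rng.uniform(6, 8) * sd
            if (df[var] >= 0).all() and value < 0:
                value = mu + rng.uniform(6, 8) * sd
            df.loc[i, var] = round(float(value), 2)
            truth.extreme_subjects.add(subjects[i])

    truth.validate()
    return df, truth


# ---------------------------------------------------------------------------
# feature-table generation
# ---------------------------------------------------------------------------


def generate_feature_tables(
    config: SimConfig,
    truth: GroundTruth,
    reference: PathwayReference | None = None,
) -> dict[tuple[str, str], FeatureTable]:
    """Generate per-(mode, source) feature tables with planted structure.

    Every reference compound is rendered as its primary adduct (plus a random
    subset of secondary adducts) with ppm mass noise; background features are
    unassigned. Intensities are log-normal on the raw scale: a per-feature
    base abundance, subject-level biological noise, planted per-cluster log2
    shifts on pathway features, planted within-cluster clinical-metabolite
    association terms, per-study batch location/scale shifts, inflated-noise
    outlier samples, and multiplicative replicate noise at the configured CV.

    Returns a dict keyed by (mode, source).
    """
    config.validate()
    if reference is None:
        reference = make_toy_pathway_reference()
    if not reference.compounds:
        raise ValueError("empty pathway reference")
    for mode in config.modes:
        if mode not in reference.adducts:
            raise ValueError(f"mode {mode!r} absent from the adduct registry")
    for pw in config.planted_pathways:
        if pw not in reference.pathways:
            raise ValueError(f"planted effect on unknown pathway {pw!r}")
    for pw, assoc in config.planted_associations.items():
        if pw not in reference.pathways:
            raise ValueError(f"planted association on unknown pathway {pw!r}")
        if truth.subject_z is not None and assoc.clinical_var not in truth.subject_z.columns:
            raise ValueError(f"association variable {assoc.clinical_var!r} not simulated")

    rng = np.random.default_rng([config.seed, 1])
    subjects = list(truth.subject_cluster)
    labels = np.array([truth.subject_cluster[s] for s in subjects])
    study_of = truth.subject_study

    # compound -> planted (cluster, effect) contributions, via its pathways
    compound_effects: dict[str, list[tuple[int, float]]] = {}
    compound_assoc: dict[str, list[PlantedAssociation]] = {}
    for pw, (cluster, effect) in config.planted_pathways.items():
        if cluster >= config.k:
            raise ValueError(f"planted effect on unknown cluster {cluster}")
        for cid in reference.pathways[pw]:
            compound_effects.setdefault(cid, []).append((cluster, effect))
    for pw, assoc in config.planted_associations.items():
        for cid in reference.pathways[pw]:
            compound_assoc.setdefault(cid, []).append(assoc)

    def pathway_of(cid: str) -> str | None:
        planted = [pw for pw in config.planted_pathways if cid in reference.pathways[pw]]
        if planted:
            return sorted(planted)[0]
        containing = sorted(pw for pw, m in reference.pathways.items() if cid in m)
        return containing[0] if containing else None

    # outlier samples are drawn once per cohort (pre-analytical causes show up
    # in both ionization modes), with per-mode inflated-noise realizations
    n_out = int(round(config.outlier_sample_rate * len(subjects)))
    out_idx = rng.choice(len(subjects), size=n_out, replace=False) if n_out else np.array([], dtype=int)
    truth.outlier_subjects.update(subjects[i] for i in out_idx)

    tables: dict[tuple[str, str], FeatureTable] = {}
    for mode, mc in sorted(config.modes.items()):
        adducts = reference.adducts[mode]
        primary = next(a for a in adducts if a.is_primary)
        # true (latent) feature catalogue for this mode
        latent: list[tuple[str, float, float, str | None, str | None]] = []
        # (latent id, true mz, true rt, compound, adduct)
        for cid in sorted(reference.compounds):
            mass = reference.compounds[cid][1]
            renders = [primary] + [a for a in adducts if not a.is_primary and rng.random() < 0.4]
            for add in renders:
                mz = mass + add.shift
                if mz <= 50:
                    continue
                rt = float(rng.uniform(30, 600))
                latent.append((f"{cid}|{add.name}", mz, rt, cid, add.name))
        for i in range(mc.n_background_features):
            latent.append(
                (f"bg{i:05d}", float(rng.uniform(85, 1275)), float(rng.uniform(30, 600)), None, None)
            )

        n_feat = len(latent)
        base = rng.normal(config.feature_base_mean, config.feature_base_sd, size=n_feat)

        # subject-level true log2 intensities (before batch/outlier/replicates)
        log2_subj = (
            base[None, :]
            + rng.normal(0.0, config.subject_log2_sd, size=(len(subjects), n_feat))
        )
        for j, (_, _, _, cid, _) in enumerate(latent):
            if cid is None:
                continue
            for cluster, effect in compound_effects.get(cid, ()):
                log2_subj[labels == cluster, j] += effect
            for assoc in compound_assoc.get(cid, ()):
                if truth.subject_z is None:
                    continue
                m = labels == assoc.cluster
                zvals = truth.subject_z.loc[np.array(subjects)[m], assoc.clinical_var]
                log2_subj[m, j] += assoc.slope * zvals.to_numpy()

        # multivariate outlier samples: inflated independent noise
        for i in out_idx:
            log2_subj[i] = log2_subj[i] + rng.normal(0, config.outlier_log2_sd, size=n_feat)

        # batch location/scale shifts on the log2 scale, around the feature base
        for study, shift in config.studies.items():
            m = np.array([study_of.get(s) == study for s in subjects])
            if not m.any():
                continue
            log2_subj[m] = (
                base[None, :]
                + (log2_subj[m] - base[None, :]) * shift.scale
                + shift.location
            )

        # latent features present in every source; assigned features always are
        shared = rng.random(n_feat) < config.shared_background_fraction
        shared[[j for j, f in enumerate(latent) if f[3] is not None]] = True

        for source, members in sorted(config.sources.items()):
            m_subj = np.array([study_of.get(s) in members for s in subjects])
            src_subjects = [s for s, keep in zip(subjects, m_subj) if keep]
            if not src_subjects:
                continue
            keep_j = [j for j in range(n_feat) if shared[j] or rng.random() < 0.5]
            feats = []
            for rank, j in enumerate(keep_j):
                _, mz_true, rt_true, cid, add = latent[j]
                mz = mz_true * (1 + rng.normal(0, mc.ppm_noise_sd) * 1e-6)
                rt = max(0.0, rt_true + rng.normal(0, 5.0))
                fid = f"{mode[0].upper()}{source[0].upper()}{rank:05d}"
                feats.append((fid, mz, rt, j))
                key = f"{mode}:{fid}"
                if cid is not None:
                    truth.feature_compound[key] = (cid, add, pathway_of(cid))
                    if cid in compound_effects:
                        truth.differential_features.add(key)

            sub_idx = [i for i, keep in enumerate(m_subj) if keep]
            log2_src = log2_subj[np.ix_(sub_idx, [f[3] for f in feats])]
            mean_raw = np.power(2.0, log2_src)

            reps = mc.n_replicates
            inj_ids, inj_samples, blocks = [], [], []
            for r in range(1, reps + 1):
                noise = (
                    1.0 + mc.replicate_cv * rng.standard_normal(mean_raw.shape)
                    if mc.replicate_cv > 0
                    else np.ones_like(mean_raw)
                )
                blocks.append(np.maximum(mean_raw * noise, 0.0))
                inj_ids.extend(f"{s}_{r}" for s in src_subjects)
                inj_samples.extend(src_subjects)
            # interleave so each sample's replicates are adjacent
            inten = np.vstack(blocks)
            order = np.argsort(np.repeat(np.arange(len(src_subjects)), 1).tolist() * reps, kind="stable")
            inten = inten[order]
            inj_ids = [inj_ids[i] for i in order]
            inj_samples = [inj_samples[i] for i in order]

            features = pd.DataFrame(
                [(f[0], f[1], f[2]) for f in feats], columns=["feature_id", "mz", "rt"]
            )
            tables[(mode, source)] = FeatureTable(
                mode=mode,
                features=features,
                intensities=pd.DataFrame(
                    inten, index=inj_ids, columns=list(features["feature_id"])
                ),
                sample_of=pd.Series(inj_samples, index=inj_ids),
                batch_of=pd.Series({s: study_of[s] for s in src_subjects}),
            )
    return tables
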