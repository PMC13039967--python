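"""m/z feature annotation and permutation pathway enrichment.

Features are annotated against a compound/pathway reference by accurate-mass
matching to common electrospray adducts within a ppm tolerance. Pathway
enrichment follows the mummichog logic: the significant feature list is
compared against the full quality-filtered background by drawing random
feature sets of the same size and counting, per pathway, how often the random
overlap (in distinct compounds, primary ions enforced) reaches the observed
one. Reported p-values use add-one smoothing, so they are never exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Adduct",
    "PathwayReference",
    "AnnotationRecord",
    "EnrichmentResult",
    "PROTON_MASS",
    "default_adduct_registry",
    "make_toy_pathway_reference",
    "annotate_features",
    "enrich_pathways",
]

# charge-carrier monoisotopic masses (Da), charge-adjusted
PROTON_MASS = 1.007276
NA_MASS = 22.989218
NH4_MASS = 18.033823
CL_MASS = 34.969402
WATER_MASS = 18.010565


@dataclass(frozen=True)
class Adduct:
    name: str
    shift: float  # Da added to the neutral monoisotopic mass
    is_primary: bool = False


def default_adduct_registry() -> dict[str, list[Adduct]]:
    """Common ESI adducts per mode; the primary ion of each mode is first."""
    return {
        "hilic_pos": [
            Adduct("M+H", PROTON_MASS, is_primary=True),
            Adduct("M+Na", NA_MASS),
            Adduct("M+NH4", NH4_MASS),
            Adduct("M+H-H2O", PROTON_MASS - WATER_MASS),
        ],
        "c18_neg": [
            Adduct("M-H", -PROTON_MASS, is_primary=True),
            Adduct("M+Cl", CL_MASS),
            Adduct("M-H-H2O", -PROTON_MASS - WATER_MASS),
        ],
    }


@dataclass
class PathwayReference:
    """Pathways mapped to compounds with monoisotopic masses.

    compounds: id -> (display name, monoisotopic mass in Da)
    pathways: pathway name -> set of compound ids
    adducts: mode -> adduct list (at least one primary per mode)
    """

    compounds: dict[str, tuple[str, float]]
    pathways: dict[str, frozenset[str]]
    adducts: dict[str, list[Adduct]] = field(default_factory=default_adduct_registry)

    def __post_init__(self) -> None:
        for cid, (_, mass) in self.compounds.items():
            if mass <= 0:
                raise ValueError(f"non-positive mass for compound {cid!r}")
        for pw, members in self.pathways.items():
            unknown = set(members) - set(self.compounds)
            if unknown:
                raise ValueError(f"pathway {pw!r} references unknown compounds {unknown}")
        for mode, adds in self.adducts.items():
            if not any(a.is_primary for a in adds):
                raise ValueError(f"mode {mode!r} has no primary adduct")

    # -- JSON round trip ----------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "compounds": {k: {"name": n, "mass": m} for k, (n, m) in self.compounds.items()},
            "pathways": {k: sorted(v) for k, v in self.pathways.items()},
            "adducts": {
                mode: [
                    {"name": a.name, "shift": a.shift, "is_primary": a.is_primary}
                    for a in adds
                ]
                for mode, adds in self.adducts.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PathwayReference":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            compounds={k: (v["name"], float(v["mass"])) for k, v in doc["compounds"].items()},
            pathways={k: frozenset(v) for k, v in doc["pathways"].items()},
            adducts={
                mode: [Adduct(a["name"], float(a["shift"]), bool(a["is_primary"])) for a in adds]
                for mode, adds in doc["adducts"].items()
            },
        )


# ---------------------------------------------------------------------------
# packaged toy reference
# ---------------------------------------------------------------------------

# (compound id, elemental formula, monoisotopic mass in Da); masses computed
# from IUPAC isotopic masses and cross-checked against rdkit ExactMolWt.
_TOY_COMPOUNDS: list[tuple[str, str, float]] = [
    ("tryptophan", "C11H12N2O2", 204.08988),
    ("kynurenine", "C10H12N2O3", 208.08479),
    ("serotonin", "C10H12N2O", 176.09496),
    ("indole-3-acetaldehyde", "C10H9NO", 159.06841),
    ("kynurenic acid", "C10H7NO3", 189.04259),
    ("5-hydroxytryptophan", "C11H12N2O3", 220.08479),
    ("indole-3-acetate", "C10H9NO2", 175.06333),
    ("anthranilate", "C7H7NO2", 137.04768),
    ("3-hydroxykynurenine", "C10H12N2O4", 224.07971),
    ("melatonin", "C13H16N2O2", 232.12118),
    ("leucine", "C6H13NO2", 131.09463),
    ("valine", "C5H11NO2", 117.07898),
    ("3-methyl-2-oxobutanoate", "C5H8O3", 116.04734),
    ("4-methyl-2-oxopentanoate", "C6H10O3", 130.06299),
    ("methylmalonate", "C4H6O4", 118.02661),
    ("3-hydroxyisobutyrate", "C4H8O3", 104.04734),
    ("acetoacetate", "C4H6O3", 102.03169),
    ("butanoate", "C4H8O2", 88.05243),
    ("3-hydroxybutanoate", "C4H8O3", 104.04734),
    ("succinate", "C4H6O4", 118.02661),
    ("2-oxoglutarate", "C5H6O5", 146.02152),
    ("4-aminobutanoate", "C4H9NO2", 103.06333),
    ("fumarate", "C4H4O4", 116.01096),
    ("propanoate", "C3H6O2", 74.03678),
    ("lactate", "C3H6O3", 90.03169),
    ("beta-alanine", "C3H7NO2", 89.04768),
    ("propane-1,2-diol", "C3H8O2", 76.05243),
    ("2-hydroxybutanoate", "C4H8O3", 104.04734),
    ("pantothenate", "C9H17NO5", 219.11067),
    ("aspartate", "C4H7NO4", 133.03751),
    ("serine", "C3H7NO3", 105.04259),
    ("pantoate", "C6H12O4", 148.07356),
    ("cysteine", "C3H7NO2S", 121.01975),
    ("dihydrouracil", "C4H6N2O2", 114.04293),
    ("urate", "C5H4N4O3", 168.02834),
    ("hypoxanthine", "C5H4N4O", 136.03851),
    ("xanthine", "C5H4N4O2", 152.03343),
    ("adenine", "C5H5N5", 135.05450),
    ("guanine", "C5H5N5O", 151.04941),
    ("inosine", "C10H12N4O5", 268.08077),
    ("adenosine", "C10H13N5O4", 267.09675),
    ("allantoin", "C4H6N4O3", 158.04399),
    ("5-hydroxyisourate", "C5H4N4O4", 184.02325),
]

_TOY_PATHWAYS: dict[str, tuple[str, ...]] = {
    "tryptophan metabolism": (
        "tryptophan", "kynurenine", "serotonin", "indole-3-acetaldehyde",
        "kynurenic acid", "5-hydroxytryptophan", "indole-3-acetate",
        "anthranilate", "3-hydroxykynurenine", "melatonin",
    ),
    "branched-chain amino acid degradation": (
        "leucine", "valine", "3-methyl-2-oxobutanoate", "4-methyl-2-oxopentanoate",
        "methylmalonate", "3-hydroxyisobutyrate", "acetoacetate",
    ),
    "butanoate metabolism": (
        "butanoate", "3-hydroxybutanoate", "acetoacetate", "succinate",
        "2-oxoglutarate", "4-aminobutanoate", "fumarate",
    ),
    "propanoate metabolism": (
        "propanoate", "lactate", "beta-alanine", "propane-1,2-diol",
        "2-hydroxybutanoate", "methylmalonate", "succinate",
    ),
    "pantothenate and CoA biosynthesis": (
        "pantothenate", "aspartate", "serine", "pantoate", "cysteine",
        "dihydrouracil", "beta-alanine", "valine",
    ),
    "purine metabolism": (
        "urate", "hypoxanthine", "xanthine", "adenine", "guanine",
        "inosine", "adenosine", "allantoin", "5-hydroxyisourate",
    ),
}


def make_toy_pathway_reference() -> PathwayReference:
    """Fixed, versioned six-pathway reference with real monoisotopic masses.

    Covers tryptophan, branched-chain amino acid degradation, butanoate,
    propanoate, pantothenate/CoA biosynthesis and purine metabolism; every
    pathway carries at least three compounds, so all are eligible for
    enrichment reporting. Calling twice returns identical content.
    """
    compounds = {cid: (cid, mass) for cid, _, mass in _TOY_COMPOUNDS}
    pathways = {name: frozenset(members) for name, members in _TOY_PATHWAYS.items()}
    return PathwayReference(compounds=compounds, pathways=pathways)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationRecord:
    feature_id: str
    compound: str
    adduct: str
    ppm_error: float
    confidence_level: int  # Schymanski 1 (confirmed) .. 5 (exact mass only)


def _as_feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame(features, columns=["feature_id", "mz"])


def annotate_features(
    features,
    reference: PathwayReference,
    mode: str,
    ppm_tol: float = 5.0,
    confirmed: set[str] | None = None,
) -> list[AnnotationRecord]:
    """Accurate-mass annotation of features against the reference compounds.

    For each mode adduct the predicted m/z is ``mass + shift``; a hit requires
    ``|observed - predicted| / predicted * 1e6 <= ppm_tol``. Features named in
    ``confirmed`` (library-confirmed identities) are reported at confidence
    level 1, mass-match-only hits at level 5.
    """
    if mode not in reference.adducts:
        raise ValueError(f"mode {mode!r} not in the adduct registry")
    feats = _as_feature_frame(features)
    confirmed = confirmed or set()

    preds = []  # (predicted_mz, compound, adduct)
    for cid, (_, mass) in reference.compounds.items():
        for add in reference.adducts[mode]:
            pred = mass + add.shift
            if pred > 0:
                preds.append((pred, cid, add.name))
    preds.sort()
    pred_mz = np.array([p[0] for p in preds])

    records: list[AnnotationRecord] = []
    for fid, mz in zip(feats["feature_id"], feats["mz"]):
        w = mz * ppm_tol * 1e-6 * 2
        lo = np.searchsorted(pred_mz, mz - w, side="left")
        hi = np.searchsorted(pred_mz, mz + w, side="right")
        for k in range(lo, hi):
            pred, cid, adduct = preds[k]
            ppm = (mz - pred) / pred * 1e6
            if abs(ppm) <= ppm_tol:
                records.append(
                    AnnotationRecord(
                        feature_id=str(fid),
                        compound=cid,
                        adduct=adduct,
                        ppm_error=float(ppm),
                        confidence_level=1 if fid in confirmed else 5,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    n_significant_hits: int
    n_detected_in_pathway: int
    empirical_p: float
    B: int

    @property
    def ratio(self) -> str:
        return f"{self.n_significant_hits}/{self.n_detected_in_pathway}"


def enrich_pathways(
    significant_ids,
    background_table,
    reference: PathwayReference,
    mode: str,
    B: int = 1000,
    min_overlap: int = 3,
    seed: int | None = None,
    ppm_tol: float = 5.0,
) -> list[EnrichmentResult]:
    """Permutation pathway enrichment of a significant set against a background.

    The background is annotated; a compound counts as hit only through features
    matching a *primary* adduct of the mode. The observed statistic per pathway
    is the number of distinct significant compounds it contains. The null draws
    ``B`` feature sets of the same size uniformly without replacement from the
    background and recomputes the overlap; ``empirical_p = (1 + #{null >=
    observed}) / (B + 1)``. Pathways are reported only when the observed
    overlap reaches ``min_overlap``; the detected denominator is the number of
    distinct pathway compounds present anywhere in the background.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    bg = _as_feature_frame(background_table)
    bg_ids = [str(f) for f in bg["feature_id"]]
    sig = {str(s) for s in significant_ids}
    missing = sig - set(bg_ids)
    if missing:
        raise ValueError(f"significant ids not in background: {sorted(missing)[:3]}")
    if len(sig) > len(bg_ids):
        raise ValueError("background smaller than the significant set")

    records = annotate_features(bg, reference, mode, ppm_tol=ppm_tol)
    primary = {a.name for a in reference.adducts[mode] if a.is_primary}
    feat_compounds: dict[str, set[str]] = {}
    for rec in records:
        if rec.adduct in primary:
            feat_compounds.setdefault(rec.feature_id, set()).add(rec.compound)

    index = {fid: i for i, fid in enumerate(bg_ids)}
    n_bg = len(bg_ids)
    compound_ids = sorted({c for s in feat_compounds.values() for c in s})
    comp_index = {c: i for i, c in enumerate(compound_ids)}
    # incidence: background feature -> detected compounds
    inc = np.zeros((n_bg, len(compound_ids)), dtype=bool)
    for fid, comps in feat_compounds.items():
        for c in comps:
            inc[index[fid], comp_index[c]] = True

    detected = {
        pw: [comp_index[c] for c in members if c in comp_index]
        for pw, members in reference.pathways.items()
    }

    sig_mask = np.zeros(n_bg, dtype=bool)
    for fid in sig:
        sig_mask[index[fid]] = True
    sig_compounds = inc[sig_mask].any(axis=0)

    rng = np.random.default_rng(seed)
    null_hits = {pw: np.zeros(B, dtype=int) for pw in detected}
    n_sig = len(sig)
    for b in range(B):
        draw = rng.choice(n_bg, size=n_sig, replace=False)
        covered = inc[draw].any(axis=0)
        for pw, cols in detected.items():
            null_hits[pw][b] = int(covered[cols].sum())

    results = []
    for pw, cols in detected.items():
        obs = int(sig_compounds[cols].sum())
        if obs < min_overlap:
            continue
        p = (1 + int((null_hits[pw] >= obs).sum())) / (B + 1)
        results.append(
            EnrichmentResult(
                pathway=pw,
                n_significant_hits=obs,
                n_detected_in_pathway=len(cols),
                empirical_p=p,
                B=B,
            )
        )
    results.sort(key=lambda r: (r.empirical_p, r.pathway))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular form of enrichment results (bar-chart ready)."""
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "hits": r.n_significant_hits,
                "detected": r.n_detected_in_pathway,
                "ratio": r.ratio,
                "empirical_p": r.empirical_p,
                "B": r.B,
            }
            for r in results
        ]
    )
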