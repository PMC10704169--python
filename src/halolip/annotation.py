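"""Library matching, unique-lipid collapsing, semi-quantification, summaries.

Features carrying MS2 are scored against the in-silico library. The total
score is the unweighted mean of four components, each in [0, 1] and
reported on a 0-100 scale:

* MS1 similarity  exp(-0.5 (dm / sigma)^2) with sigma = ms1_tol / 2,
* forward dot product on square-root intensities,
* reverse dot product (normalized over matched query signal only),
* matched fraction of library fragments.

Candidates are considered only within the MS1 tolerance (default 0.01 Da)
and accepted above a 70% total score. Accepted annotations are collapsed
across adducts and RT isomers to unique lipids, which are semi-quantified
against a spiked internal standard (response factors fixed at 1).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from halolip.features_io import AlignedFeature, SampleMetadata
from halolip.lipid_library import CLASS_GROUPS, LibrarySpectrum

DEFAULT_MS1_TOL = 0.01   # Da
DEFAULT_MS2_TOL = 0.05   # Da
DEFAULT_SCORE_THRESHOLD = 70.0


@dataclass
class AnnotationResult:
    feature_id: str
    library_name: str
    lipid_class: str
    adduct: str
    ms1_error: float
    ms1_similarity: float
    dot_product: float
    reverse_dot: float
    matched_fraction: float
    total_score: float
    accepted: bool
    tentative: bool = False
    ms1_only: bool = False


def _greedy_match(
    query: list[tuple[float, float]],
    library: list[tuple[float, float]],
    tol: float,
) -> list[tuple[int, int]]:
    """Greedy nearest-m/z peak pairing within tol, each peak used once."""
    cands = []
    for i, (mq, _) in enumerate(query):
        for j, (ml, _) in enumerate(library):
            d = abs(mq - ml)
            if d <= tol:
                cands.append((d, i, j))
    cands.sort()
    used_q: set[int] = set()
    used_l: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_q or j in used_l:
            continue
        used_q.add(i)
        used_l.add(j)
        pairs.append((i, j))
    return pairs


def score_spectra(
    query: list[tuple[float, float]],
    library: list[tuple[float, float]],
    ms2_tol: float = DEFAULT_MS2_TOL,
) -> tuple[float, float, float]:
    """(dot, reverse dot, matched fraction), all in [0, 1].

    Intensities are square-root transformed before the dot products.
    """
    if not query or not library:
        return 0.0, 0.0, 0.0
    pairs = _greedy_match(query, library, ms2_tol)
    sq = np.sqrt([i for _, i in query])
    sl = np.sqrt([i for _, i in library])
    s = sum(sq[i] * sl[j] for i, j in pairs)
    norm_q = float(np.linalg.norm(sq))
    norm_l = float(np.linalg.norm(sl))
    dot = s / (norm_q * norm_l) if s else 0.0
    matched_q = float(np.linalg.norm([sq[i] for i, _ in pairs])) if pairs else 0.0
    rev = s / (matched_q * norm_l) if matched_q else 0.0
    frac = len(pairs) / len(library)
    return float(dot), float(rev), float(frac)


def class_from_name(entry: LibrarySpectrum) -> str:
    """Lipid class of a library entry (species ref or parsed from NAME)."""
    if entry.species is not None:
        return entry.species.lipid_class
    head = entry.name.split(";")[0].strip()
    first = head.split()[0] if head else ""
    if first in CLASS_GROUPS:
        return first
    if first.startswith("AR(") or first.startswith("Ext-AR(") \
            or first.startswith("diExt-AR("):
        return "AR"
    if first.startswith("MK_"):
        return "MK"
    if first.endswith("BR"):
        return "BR"
    return first


def match_feature(
    feature: AlignedFeature,
    library: Sequence[LibrarySpectrum],
    ms1_tol: float = DEFAULT_MS1_TOL,
    ms2_tol: float = DEFAULT_MS2_TOL,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    required_diagnostics: dict[str, float] | None = None,
) -> list[AnnotationResult]:
    """Score a feature against all library entries within the MS1 tolerance.

    Returns candidates ranked by total score (ties broken by smaller MS1
    error, then lexicographic name). A feature without MS2 yields MS1-only
    candidates that are flagged and never accepted.
    ``required_diagnostics`` maps lipid class -> diagnostic fragment m/z;
    an accepted hit missing that fragment is marked tentative.
    """
    required_diagnostics = (
        required_diagnostics if required_diagnostics is not None
        else {"PI": 261.038}
    )
    sigma = ms1_tol / 2.0
    results = []
    for entry in library:
        dm = feature.mz - entry.precursor_mz
        if abs(dm) > ms1_tol:
            continue
        ms1_sim = math.exp(-0.5 * (dm / sigma) ** 2)
        cls = class_from_name(entry)
        if feature.ms2 is None:
            results.append(
                AnnotationResult(
                    feature.feature_id, entry.name, cls, entry.adduct,
                    dm, ms1_sim, 0.0, 0.0, 0.0,
                    total_score=25.0 * ms1_sim,
                    accepted=False, ms1_only=True,
                )
            )
            continue
        dot, rev, frac = score_spectra(feature.ms2.peaks, entry.peaks, ms2_tol)
        total = 100.0 * (ms1_sim + dot + rev + frac) / 4.0
        accepted = total > threshold
        tentative = False
        diag = required_diagnostics.get(cls)
        if accepted and diag is not None:
            tentative = not any(
                abs(mz - diag) <= ms2_tol for mz, _ in feature.ms2.peaks
            )
        results.append(
            AnnotationResult(
                feature.feature_id, entry.name, cls, entry.adduct,
                dm, ms1_sim, dot, rev, frac, total, accepted, tentative,
            )
        )
    results.sort(key=lambda r: (-r.total_score, abs(r.ms1_error), r.library_name))
    return results


def annotate_features(
    features: Sequence[AlignedFeature],
    library: Sequence[LibrarySpectrum],
    ms1_tol: float = DEFAULT_MS1_TOL,
    ms2_tol: float = DEFAULT_MS2_TOL,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    curation_blacklist: Iterable[str] = (),
) -> list[AnnotationResult]:
    """Best accepted annotation per feature (manual-curation list honoured).

    ``curation_blacklist`` holds feature ids rejected on manual review;
    they are skipped, standing in for expert curation of false positives.
    """
    blacklist = set(curation_blacklist)
    out = []
    for f in features:
        if f.feature_id in blacklist or f.ms2 is None:
            continue
        ranked = match_feature(f, library, ms1_tol, ms2_tol, threshold)
        if ranked and ranked[0].accepted:
            out.append(ranked[0])
    return out


# ---------------------------------------------------------------------------
# Unique lipids
# ---------------------------------------------------------------------------

@dataclass
class UniqueLipid:
    """One lipid species collapsed over adduct forms and RT isomers."""

    name: str                       # library species name (class + core)
    lipid_class: str
    member_features: list[str] = field(default_factory=list)
    abundance: dict[str, float] = field(default_factory=dict)

    @property
    def group(self) -> str:
        return CLASS_GROUPS.get(self.lipid_class, "other")


def collapse_unique(
    annotations: Sequence[AnnotationResult],
    features: Sequence[AlignedFeature] | None = None,
    adducts: tuple[str, ...] = ("[M+H]+", "[M+NH4]+"),
) -> list[UniqueLipid]:
    """Group accepted annotations into unique lipids.

    The species identity is the library name stripped of the adduct tag,
    so both integration adducts and RT isomers of one species merge; raw
    intensities of member features are summed per sample.
    """
    by_feature = {f.feature_id: f for f in (features or [])}
    groups: dict[str, UniqueLipid] = {}
    for ann in annotations:
        if not ann.accepted:
            raise ValueError("collapse_unique expects accepted annotations only")
        if ann.adduct not in adducts:
            continue
        species = ann.library_name.split(";")[0].strip()
        ul = groups.setdefault(species, UniqueLipid(species, ann.lipid_class))
        if ul.lipid_class != ann.lipid_class:
            raise ValueError(
                f"conflicting class assignment within group {species!r}"
            )
        ul.member_features.append(ann.feature_id)
        feat = by_feature.get(ann.feature_id)
        if feat is not None:
            for s, v in feat.intensities.items():
                ul.abundance[s] = ul.abundance.get(s, 0.0) + v
    return sorted(groups.values(), key=lambda u: u.name)


def semi_quantify(
    lipids: Sequence[UniqueLipid],
    features: Sequence[AlignedFeature],
    is_mz: float,
    spike_amount: float = 1.0,
    mz_tol: float = DEFAULT_MS1_TOL,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Abundance = intensity / IS intensity x spike amount, per sample.

    The internal standard feature is located by m/z; it must carry signal
    in every requested sample (response factors are fixed at 1 because
    compound-specific standards are unavailable).
    """
    is_candidates = [f for f in features if abs(f.mz - is_mz) <= mz_tol]
    if not is_candidates:
        raise ValueError(f"internal standard not found at m/z {is_mz}")
    is_feature = max(
        is_candidates, key=lambda f: max(f.intensities.values(), default=0.0)
    )
    if samples is None:
        samples = list(is_feature.intensities)
    for s in samples:
        if is_feature.intensities.get(s, 0.0) <= 0:
            raise ValueError(f"internal standard missing in sample {s!r}")
    data = {}
    for ul in lipids:
        data[ul.name] = [
            ul.abundance.get(s, 0.0) / is_feature.intensities[s] * spike_amount
            for s in samples
        ]
    return pd.DataFrame(data, index=list(samples)).T


def class_summary(lipids: Sequence[UniqueLipid]) -> dict[str, dict[str, int]]:
    """Counts per lipid class and per class group; totals must reconcile."""
    per_class: dict[str, int] = defaultdict(int)
    per_group: dict[str, int] = defaultdict(int)
    for ul in lipids:
        per_class[ul.lipid_class] += 1
        per_group[ul.group] += 1
    return {
        "per_class": dict(per_class),
        "per_group": dict(per_group),
        "total": {"unique_lipids": len(lipids)},
    }


def summary_total(per_group: dict[str, int]) -> int:
    return sum(per_group.values())


def write_annotation_report(
    annotations: Sequence[AnnotationResult], path: str
) -> None:
    rows = [
        {
            "feature_id": a.feature_id,
            "species": a.library_name,
            "class": a.lipid_class,
            "adduct": a.adduct,
            "ms1_error_da": round(a.ms1_error, 5),
            "ms1_similarity": round(a.ms1_similarity, 4),
            "dot_product": round(a.dot_product, 4),
            "reverse_dot": round(a.reverse_dot, 4),
            "matched_fraction": round(a.matched_fraction, 4),
            "total_score": round(a.total_score, 2),
            "accepted": a.accepted,
            "tentative": a.tentative,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
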