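"""Feature-table and MS2 I/O plus alignment-stage filters.

Inputs follow the layout of an aligned untargeted LC-MS export: one row
per aligned feature (id, m/z, RT in minutes, one intensity column per
sample) with a side table assigning each sample a role (sample / blank /
qc), strain and replicate. MS2 spectra travel as MGF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf


@dataclass
class Ms2Spectrum:
    """One MS2 spectrum: precursor m/z, RT (minutes), peak list."""

    precursor_mz: float
    rt: float
    peaks: list[tuple[float, float]]
    source: str = ""
    feature_id: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        if any(i <= 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be positive")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass
class AlignedFeature:
    """One aligned LC-MS feature across the sample cohort."""

    feature_id: str
    mz: float
    rt: float
    intensities: dict[str, float]
    ms2: Ms2Spectrum | None = None
    adduct: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: m/z must be positive")
        if self.rt < 0:
            raise ValueError(f"{self.feature_id}: RT must be non-negative")
        for s, v in self.intensities.items():
            if v < 0:
                raise ValueError(f"{self.feature_id}: negative intensity in {s}")


@dataclass
class FilterConfig:
    """Alignment/filter parameters (defaults: standard untargeted settings)."""

    min_peak_height: float = 3000.0
    align_rt_tol: float = 0.7      # min
    align_mz_tol: float = 0.05     # Da
    blank_factor: float = 10.0
    rt_correction_max_dev: float = 0.8  # min
    mass_slice_width: float = 0.1  # Da; peak-detection metadata only

    def __post_init__(self) -> None:
        for name in ("min_peak_height", "align_rt_tol", "align_mz_tol",
                     "blank_factor", "rt_correction_max_dev"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class SampleMetadata:
    """Sample roles: which columns are biological samples, blanks, QC."""

    roles: dict[str, str]                      # sample_id -> sample|blank|qc
    strains: dict[str, str] = field(default_factory=dict)
    replicates: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values()} - {"sample", "blank", "qc"}
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == "sample"]

    @property
    def blank_ids(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == "blank"]


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    roles = dict(zip(df["sample_id"], df["role"]))
    strains = {}
    if "strain" in df.columns:
        strains = {
            sid: s for sid, s in zip(df["sample_id"], df["strain"])
            if pd.notna(s) and str(s).strip()
        }
    reps = {}
    if "replicate" in df.columns:
        for sid, rep in zip(df["sample_id"], df["replicate"]):
            if pd.notna(rep) and str(rep).strip():
                reps[sid] = int(float(rep))
    return SampleMetadata(roles, strains, reps)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s,
            "role": r,
            "strain": meta.strains.get(s, ""),
            "replicate": meta.replicates.get(s, ""),
        }
        for s, r in meta.roles.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, sep: str | None = None) -> list[AlignedFeature]:
    """Read a feature table (CSV/TSV: id, mz, rt_min, then sample columns)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = ["id", "mz", "rt_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing required columns: {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    features = []
    for row_idx, row in df.iterrows():
        for c in sample_cols:
            v = row[c]
            if pd.isna(v):
                raise ValueError(
                    f"non-numeric intensity at line {row_idx + 2}, "
                    f"column {c!r} (feature {row['id']})"
                )
        features.append(
            AlignedFeature(
                feature_id=str(row["id"]),
                mz=float(row["mz"]),
                rt=float(row["rt_min"]),
                intensities={c: float(row[c]) for c in sample_cols},
            )
        )
    return features


def write_feature_table(features: Sequence[AlignedFeature], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    if not features:
        raise ValueError("no features to write")
    samples = list(features[0].intensities)
    rows = []
    for f in features:
        row = {"id": f.feature_id, "mz": round(f.mz, 4), "rt_min": round(f.rt, 2)}
        row.update({s: f.intensities.get(s, 0.0) for s in samples})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read MGF; RTINSECONDS is converted to minutes internally."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pep = params["pepmass"]
            prec = pep[0] if isinstance(pep, (tuple, list)) else float(pep)
            rt_s = float(params.get("rtinseconds", 0.0))
            title = str(params.get("title", ""))
            peaks = list(zip(entry["m/z array"], entry["intensity array"]))
            spectra.append(
                Ms2Spectrum(
                    precursor_mz=float(prec),
                    rt=rt_s / 60.0,
                    peaks=[(float(m), float(i)) for m, i in peaks],
                    source=title,
                    feature_id=str(params.get("feature_id", title)),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": np.array([m for m, _ in s.peaks]),
                "intensity array": np.array([i for _, i in s.peaks]),
                "params": {
                    "title": s.source or s.feature_id,
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.rt * 60.0,
                    "feature_id": s.feature_id,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def attach_ms2(
    features: Sequence[AlignedFeature],
    spectra: Sequence[Ms2Spectrum],
    mz_tol: float = 0.05,
    rt_tol: float = 0.7,
) -> int:
    """Attach each feature's best (closest-m/z) MS2 spectrum; returns count.

    Spectra carrying a ``feature_id`` matching a feature are linked
    directly; otherwise the closest precursor within tolerances wins.
    """
    by_id = {s.feature_id: s for s in spectra if s.feature_id}
    n = 0
    for f in features:
        if f.feature_id in by_id:
            f.ms2 = by_id[f.feature_id]
            n += 1
            continue
        best, best_dm = None, mz_tol
        for s in spectra:
            dm = abs(s.precursor_mz - f.mz)
            if dm <= best_dm and abs(s.rt - f.rt) <= rt_tol:
                best, best_dm = s, dm
        if best is not None:
            f.ms2 = best
            n += 1
    return n


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def rt_correct(
    features: Sequence[AlignedFeature],
    internal_standards: Sequence[tuple[str, float, float]],
    mz_tol: float = 0.05,
    max_dev: float = 0.8,
) -> list[str]:
    """Shift feature RTs so located internal standards hit their expected RT.

    ``internal_standards`` lists (name, expected_rt_min, mz). A piecewise
    linear map through the located IS anchors is applied (constant shift
    when only one IS). Any IS deviating more than ``max_dev`` minutes is
    excluded from the fit and reported in the returned warning list.
    """
    anchors: list[tuple[float, float]] = []  # (observed rt, expected rt)
    flagged: list[str] = []
    for name, expected_rt, mz in internal_standards:
        candidates = [f for f in features if abs(f.mz - mz) <= mz_tol]
        if not candidates:
            continue
        hit = min(candidates, key=lambda f: abs(f.rt - expected_rt))
        dev = hit.rt - expected_rt
        if abs(dev) > max_dev:
            msg = (f"internal standard {name!r} deviates {dev:+.2f} min "
                   f"(> {max_dev}); excluded from RT correction")
            warnings.warn(msg)
            flagged.append(msg)
            continue
        anchors.append((hit.rt, expected_rt))
    if not anchors:
        raise ValueError("no internal standard located within tolerance")
    anchors.sort()
    obs = np.array([a for a, _ in anchors])
    exp = np.array([e for _, e in anchors])
    if len(anchors) == 1:
        shift = exp[0] - obs[0]
        for f in features:
            f.rt = max(f.rt + shift, 0.0)
    else:
        for f in features:
            f.rt = max(float(np.interp(f.rt, obs, exp)), 0.0)
    return flagged


def blank_filter(
    features: Sequence[AlignedFeature],
    meta: SampleMetadata,
    factor: float = 10.0,
) -> list[AlignedFeature]:
    """Keep features whose max sample intensity is >= factor x max blank.

    A feature absent from every blank is always kept; the ratio exactly at
    the factor is kept (only *lower* than factor-fold is filtered).
    """
    kept = []
    samples, blanks = meta.sample_ids, meta.blank_ids
    for f in features:
        s_max = max((f.intensities.get(s, 0.0) for s in samples), default=0.0)
        b_max = max((f.intensities.get(b, 0.0) for b in blanks), default=0.0)
        if b_max == 0.0 or s_max >= factor * b_max:
            kept.append(f)
    return kept


def height_filter(
    features: Sequence[AlignedFeature], min_height: float = 3000.0
) -> list[AlignedFeature]:
    """Drop features below the minimum peak height in every sample."""
    return [f for f in features
            if max(f.intensities.values(), default=0.0) >= min_height]


def coverage_stats(
    n_features: int,
    n_with_ms2: int,
    n_annotated: int,
    n_network: int,
) -> dict[str, float]:
    """Coverage percentages relative to the MS2-bearing feature count."""
    if n_with_ms2 == 0:
        raise ValueError("no MS2-bearing features; coverage undefined")
    return {
        "n_features": n_features,
        "n_with_ms2": n_with_ms2,
        "n_annotated": n_annotated,
        "pct_annotated": round(100.0 * n_annotated / n_with_ms2, 2),
        "n_network": n_network,
        "pct_network": round(100.0 * n_network / n_with_ms2, 2),
    }
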