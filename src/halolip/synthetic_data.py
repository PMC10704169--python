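"""Seeded generator of a seven-strain halobacterial lipidomics study.

Emulates the design the analysis modules expect: seven strains from
three orders grown in triplicate plus extraction blanks, an aligned
feature table with MS2 spectra, internal standards, unknown analog
features that share fragmentation with known classes but have no library
entry, blank contaminants, a ground-truth table, and a toy pre-aligned
16S alignment whose within-order similarity exceeds the between-order
similarity.

Class presence/absence per strain follows the culture survey the package
models (three-star pattern: major vs trace vs absent); unsaturation and
C25-chain parameters per strain use the study's printed percentages.
Tier semantics are a generator choice: major abundances are log-normal
(sigma = 0.3) around a class base level, trace = major / 50.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from halolip.composition import adduct_mz
from halolip.features_io import (
    AlignedFeature,
    Ms2Spectrum,
    SampleMetadata,
    write_feature_table,
    write_mgf,
    write_sample_metadata,
)
from halolip.lipid_library import (
    CoreLipid,
    LibraryConfig,
    LibrarySpectrum,
    LipidSpecies,
    build_default_library,
    load_rules,
    make_bacterioruberin,
    make_menaquinone,
    make_species,
    predict_spectrum,
)

ORDERS = {
    "Ha_argentinensis": "Halobacteriales",
    "Hf_mediterranei": "Haloferacales",
    "Hf_larsenii": "Haloferacales",
    "Hf_volcanii": "Haloferacales",
    "Ht_turkmenica": "Natrialbales",
    "Na_asiatica": "Natrialbales",
    "Nn_gari": "Natrialbales",
}

MAJOR, TRACE, ABSENT = "major", "trace", "absent"

#: Class presence tiers per strain (columns: Ha, Hf_med, Hf_lar, Hf_vol,
#: Ht, Na, Nn), transcribed from the seven-strain culture survey.
_TIER_TABLE: dict[str, tuple[str, ...]] = {
    "MK":          (MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR),
    "AR":          (MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR),
    "Me-PGP":      (MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR),
    "PG":          (MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR),
    "BR":          (MAJOR, TRACE, MAJOR, MAJOR, MAJOR, ABSENT, MAJOR),
    "PGS":         (MAJOR, MAJOR, ABSENT, ABSENT, ABSENT, ABSENT, MAJOR),
    "TGD":         (MAJOR, ABSENT, ABSENT, ABSENT, ABSENT, ABSENT, MAJOR),
    "BPG":         (MAJOR, TRACE, MAJOR, TRACE, ABSENT, ABSENT, ABSENT),
    "TGD-PA":      (MAJOR, ABSENT, ABSENT, ABSENT, ABSENT, ABSENT, ABSENT),
    "DGD-PA":      (MAJOR, MAJOR, MAJOR, MAJOR, ABSENT, ABSENT, ABSENT),
    "S-DGD-PA":    (ABSENT, MAJOR, MAJOR, MAJOR, ABSENT, ABSENT, TRACE),
    "S-DGD":       (ABSENT, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR),
    "DGD":         (TRACE, MAJOR, MAJOR, MAJOR, MAJOR, TRACE, MAJOR),
    "S-Gly-AHH":   (ABSENT, MAJOR, MAJOR, MAJOR, MAJOR, MAJOR, TRACE),
    "PE":          (ABSENT, MAJOR, MAJOR, TRACE, MAJOR, MAJOR, MAJOR),
    "MGD":         (ABSENT, ABSENT, TRACE, ABSENT, MAJOR, MAJOR, MAJOR),
    "PI":          (ABSENT, MAJOR, TRACE, TRACE, ABSENT, ABSENT, ABSENT),
    "2S-DGD":      (ABSENT, ABSENT, ABSENT, ABSENT, MAJOR, MAJOR, ABSENT),
    "2S-Gly-AHH":  (ABSENT, ABSENT, ABSENT, ABSENT, MAJOR, MAJOR, ABSENT),
    "Gly-PG":      (ABSENT, ABSENT, ABSENT, TRACE, TRACE, ABSENT, MAJOR),
    "PA":          (TRACE, TRACE, TRACE, TRACE, TRACE, TRACE, TRACE),
    "MGD-PA":      (TRACE, TRACE, TRACE, MAJOR, ABSENT, ABSENT, ABSENT),
    "S-MGD":       (ABSENT, TRACE, TRACE, TRACE, TRACE, ABSENT, ABSENT),
}

_STRAIN_ORDER = (
    "Ha_argentinensis", "Hf_mediterranei", "Hf_larsenii", "Hf_volcanii",
    "Ht_turkmenica", "Na_asiatica", "Nn_gari",
)

#: (pct cores unsaturated, fraction of unsaturated with >= 4 double bonds,
#:  pct of chains that are C25) per strain, from the study's core survey.
_CORE_PARAMS: dict[str, tuple[float, float, float]] = {
    "Ha_argentinensis": (0.32, 0.00, 0.10),
    "Hf_mediterranei": (20.72, 0.0256, 0.10),
    "Hf_larsenii": (16.00, 0.2127, 0.10),
    "Hf_volcanii": (11.17, 0.0039, 0.10),
    "Ht_turkmenica": (2.27, 0.0905, 13.44),
    "Na_asiatica": (5.01, 0.3393, 26.16),
    "Nn_gari": (3.50, 0.4443, 20.00),
}

#: Relative base abundance per lipid class (detector counts); Me-PGP and
#: PG dominate halobacterial lipidomes. The scale is set so that even
#: trace-tier species (base / 50) clear a 3,000-count detection floor:
#: the emitted table emulates a *detected* feature export.
_CLASS_BASE: dict[str, float] = {
    "AR": 4e7, "PG": 8e7, "Me-PGP": 1e8, "PGS": 1e7, "PA": 4e6, "PE": 5e6,
    "PI": 4e6, "Gly-PG": 8e6, "MGD": 8e6, "DGD": 1.2e7, "TGD": 1.5e7,
    "S-MGD": 4e6, "S-DGD": 2.5e7, "2S-DGD": 1.5e7, "S-Gly-AHH": 9e6,
    "2S-Gly-AHH": 6e6, "BPG": 6e6, "MGD-PA": 4e6, "DGD-PA": 7e6,
    "TGD-PA": 9e6, "S-DGD-PA": 8e6, "MK": 5e7, "BR": 2e7,
}

#: Internal standard: 1,2-dinonadecanoyl-sn-glycero-3-phosphocholine
#: (C19-PC), C46H92NO8P, spiked into every non-blank sample.
IS_C19PC_FORMULA = "C46H92NO8P"
IS_C19PC_MZ = 818.6633          # [M+H]+, proton convention
IS_C19PC_RT = 22.0              # min


@dataclass
class StrainProfile:
    """Ground-truth lipidome parameters of one simulated strain."""

    name: str
    order: str
    tiers: dict[str, str]
    pct_unsaturated: float
    poly_fraction: float          # among unsaturated cores
    pct_c25_chains: float
    n_unknown_analogs: int = 4

    def __post_init__(self) -> None:
        bad = set(self.tiers.values()) - {MAJOR, TRACE, ABSENT}
        if bad:
            raise ValueError(f"unknown abundance tiers: {sorted(bad)}")
        if not 0 <= self.pct_c25_chains <= 50:
            raise ValueError("C25 chain percentage must be within 0-50")

    def core_weights(self) -> dict[CoreLipid, float]:
        """Core-variant mixture reproducing the strain's chain statistics."""
        u = self.pct_unsaturated / 100.0
        e = 2.0 * self.pct_c25_chains / 100.0  # Ext-AR molecule fraction
        sat = max(1.0 - u - e, 0.0)
        w = {
            CoreLipid(20, 20, 0): sat,
            CoreLipid(20, 20, 2): u * (1.0 - self.poly_fraction),
            CoreLipid(20, 20, 5): u * self.poly_fraction,
            CoreLipid(20, 25, 0): e,
        }
        return {c: x for c, x in w.items() if x > 0}


def default_profiles() -> list[StrainProfile]:
    """The seven-strain study design with its class-presence pattern."""
    profiles = []
    for idx, strain in enumerate(_STRAIN_ORDER):
        tiers = {cls: row[idx] for cls, row in _TIER_TABLE.items()}
        unsat, poly, c25 = _CORE_PARAMS[strain]
        profiles.append(
            StrainProfile(
                name=strain,
                order=ORDERS[strain],
                tiers=tiers,
                pct_unsaturated=unsat,
                poly_fraction=poly,
                pct_c25_chains=c25,
            )
        )
    return profiles


@dataclass
class SimConfig:
    """Noise and design parameters of the simulation."""

    seed: int = 42
    n_replicates: int = 3
    n_blanks: int = 2
    mz_jitter_sigma: float = 0.005     # Da
    intensity_cv: float = 0.10
    tier_sigma: float = 0.3            # log-normal sigma of the major tier
    n_contaminants: int = 8
    n_novel_per_order: int = 5
    unknown_analog_shift: float = 14.01565  # CH2 homolog step, Da
    nh4_probability: float = 0.6
    ms2_noise_peaks: int = 3
    alignment_length: int = 600
    p_between_orders: float = 0.10     # substitutions per site, root->order
    p_within_order: float = 0.02       # order ancestor -> strain

    def __post_init__(self) -> None:
        if self.mz_jitter_sigma < 0:
            raise ValueError("m/z jitter sigma must be >= 0")


@dataclass
class SimulationResult:
    features: list[AlignedFeature]
    spectra: list[Ms2Spectrum]
    metadata: SampleMetadata
    ground_truth: pd.DataFrame
    alignment: dict[str, str]
    library: list[LibrarySpectrum]
    profiles: list[StrainProfile]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": out / "features.csv",
            "spectra": out / "spectra.mgf",
            "metadata": out / "samples.tsv",
            "ground_truth": out / "ground_truth.tsv",
            "alignment": out / "sixteen_s.fasta",
        }
        write_feature_table(self.features, paths["features"])
        write_mgf(self.spectra, paths["spectra"])
        write_sample_metadata(self.metadata, paths["metadata"])
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
        with open(paths["alignment"], "w") as fh:
            for taxon, seq in self.alignment.items():
                fh.write(f">{taxon}\n{seq}\n")
        return paths


def _strain_species(profile: StrainProfile) -> list[tuple[LipidSpecies, float]]:
    """Species emitted by one strain with their relative weights."""
    cores = profile.core_weights()
    out: list[tuple[LipidSpecies, float]] = []
    for cls, tier in profile.tiers.items():
        if tier == ABSENT:
            continue
        base = _CLASS_BASE[cls]
        if tier == TRACE:
            base = base / 50.0
        if cls == "MK":
            out.append((make_menaquinone(8, 8), base * 0.7))
            out.append((make_menaquinone(8, 7), base * 0.3))
        elif cls == "BR":
            out.append((make_bacterioruberin(0), base * 0.8))
            out.append((make_bacterioruberin(1), base * 0.2))
        else:
            n_cores = 2 if cls in ("BPG", "MGD-PA", "DGD-PA", "TGD-PA",
                                   "S-DGD-PA") else 1
            for core, w in cores.items():
                sp = make_species(cls, [core] * n_cores)
                out.append((sp, base * w))
    return out


def simulate(
    profiles: list[StrainProfile] | None = None,
    config: SimConfig | None = None,
    library_config: LibraryConfig | None = None,
) -> SimulationResult:
    """Generate the full input bundle for the analysis pipeline.

    Deterministic given the seed: features (with per-sample intensities
    and jittered m/z), MGF spectra (predicted + noise peaks), sample
    metadata, a ground-truth table linking every non-blank feature to its
    emitted species or decoy, and a toy 16S alignment.
    """
    profiles = profiles if profiles is not None else default_profiles()
    config = config or SimConfig()
    library_config = library_config or LibraryConfig()
    rng = np.random.default_rng(config.seed)
    rules = load_rules()
    library = build_default_library(library_config, rules)

    samples: list[str] = []
    meta_roles: dict[str, str] = {}
    strains_map: dict[str, str] = {}
    reps_map: dict[str, int] = {}
    for p in profiles:
        for r in range(1, config.n_replicates + 1):
            sid = f"{p.name}_r{r}"
            samples.append(sid)
            meta_roles[sid] = "sample"
            strains_map[sid] = p.name
            reps_map[sid] = r
    blanks = [f"blank_{i+1}" for i in range(config.n_blanks)]
    for b in blanks:
        meta_roles[b] = "blank"
    metadata = SampleMetadata(meta_roles, strains_map, reps_map)
    all_cols = samples + blanks

    # ------------------------------------------------------------------
    # Union of emitted (species, adduct) -> one aligned feature each
    # ------------------------------------------------------------------
    per_strain = {p.name: dict() for p in profiles}
    union: dict[tuple[str, str], LipidSpecies] = {}
    # ammonium adduct formation is head-group chemistry: decide per class
    nh4_classes = {
        cls for cls in sorted(_CLASS_BASE)
        if rng.random() < config.nh4_probability
    }
    for p in profiles:
        for sp, w in _strain_species(p):
            per_strain[p.name][sp.name] = w
            union.setdefault((sp.name, "[M+H]+"), sp)
            if sp.lipid_class in nh4_classes:
                union.setdefault((sp.name, "[M+NH4]+"), sp)

    rep_factors = {
        sid: float(rng.lognormal(0.0, config.tier_sigma)) for sid in samples
    }
    features: list[AlignedFeature] = []
    spectra: list[Ms2Spectrum] = []
    truth_rows: list[dict] = []
    fid = 0

    def emit(
        species_name: str,
        adduct: str,
        mz_true: float,
        intensities: dict[str, float],
        ms2_peaks: list[tuple[float, float]] | None,
        kind: str,
        rt: float,
    ) -> None:
        nonlocal fid
        fid += 1
        feature_id = f"F{fid:05d}"
        # the consensus m/z of an aligned feature averages one observation
        # per sample carrying the feature, so its jitter shrinks by sqrt(n)
        n_obs = max(sum(1 for v in intensities.values() if v > 0), 1)
        mz_obs = mz_true + rng.normal(
            0.0, config.mz_jitter_sigma / np.sqrt(n_obs)
        )
        spec = None
        if ms2_peaks:
            noisy = [
                (max(m + rng.normal(0.0, config.mz_jitter_sigma), 1.0),
                 max(i * (1.0 + rng.normal(0.0, config.intensity_cv)), 1e-3))
                for m, i in ms2_peaks
            ]
            for _ in range(config.ms2_noise_peaks):
                noisy.append(
                    (float(rng.uniform(100.0, mz_true)),
                     float(rng.uniform(0.5, 5.0)))
                )
            spec = Ms2Spectrum(
                precursor_mz=mz_obs, rt=rt, peaks=noisy,
                source=feature_id, feature_id=feature_id,
            )
            spectra.append(spec)
        feat = AlignedFeature(
            feature_id=feature_id, mz=mz_obs, rt=rt,
            intensities={c: intensities.get(c, 0.0) for c in all_cols},
            ms2=spec, adduct=adduct,
        )
        features.append(feat)
        truth_rows.append(
            {
                "feature_id": feature_id,
                "species": species_name,
                "adduct": adduct,
                "kind": kind,
                "mz_true": round(mz_true, 5),
            }
        )

    spectra_by_key = {
        (s.species.name, s.adduct): s for s in library if s.species is not None
    }

    for (sp_name, adduct), sp in sorted(union.items()):
        mz_true = adduct_mz(sp.neutral_mass, adduct)
        lib_spec = spectra_by_key.get((sp_name, adduct))
        if lib_spec is None:
            lib_spec = predict_spectrum(sp, adduct, rules)
        rt = float(rng.uniform(3.0, 34.0))
        intensities: dict[str, float] = {}
        for p in profiles:
            w = per_strain[p.name].get(sp_name)
            if w is None:
                continue
            level = w * (0.5 if adduct == "[M+NH4]+" else 1.0)
            for r in range(1, config.n_replicates + 1):
                sid = f"{p.name}_r{r}"
                # biomass/extraction variation scales the whole replicate;
                # per-species measurement noise is the intensity CV
                intensities[sid] = float(
                    level
                    * rep_factors[sid]
                    * rng.lognormal(0.0, config.intensity_cv)
                )
        emit(sp_name, adduct, mz_true, intensities, lib_spec.peaks,
             "library", rt)

    # ------------------------------------------------------------------
    # Unknown analogs: homolog-shifted spectra with no library entry
    # ------------------------------------------------------------------
    for p in profiles:
        emitted = [
            (name, w) for name, w in sorted(per_strain[p.name].items())
            if not name.startswith(("MK", "BR", "anhydro"))
        ]
        picks = rng.choice(len(emitted), size=min(p.n_unknown_analogs,
                                                  len(emitted)), replace=False)
        for k, pick in enumerate(sorted(picks)):
            parent_name, w = emitted[pick]
            parent = union.get((parent_name, "[M+H]+"))
            if parent is None:
                continue
            shift = config.unknown_analog_shift * (k + 1)
            parent_spec = spectra_by_key.get((parent_name, "[M+H]+"))
            if parent_spec is None:
                parent_spec = predict_spectrum(parent, "[M+H]+", rules)
            prec = parent_spec.precursor_mz + shift
            # precursor-dependent (neutral-loss) peaks shift with the
            # precursor; small diagnostic ions stay put
            peaks = [
                (m + shift if m > parent_spec.precursor_mz / 2 else m, i)
                for m, i in parent_spec.peaks
            ]
            intens = {
                f"{p.name}_r{r}": float(
                    w * 0.3 * rng.lognormal(0.0, config.tier_sigma)
                )
                for r in range(1, config.n_replicates + 1)
            }
            emit(f"analog:{parent_name}+{k+1}CH2", "[M+H]+", prec, intens,
                 peaks, "unknown_analog", float(rng.uniform(3.0, 34.0)))

    # ------------------------------------------------------------------
    # Novel lipid families: order-specific homolog series with a shared
    # fragmentation pattern and no library entry (all-unknown networks)
    # ------------------------------------------------------------------
    orders_map: dict[str, list[StrainProfile]] = {}
    for p in profiles:
        orders_map.setdefault(p.order, []).append(p)
    for order in sorted(orders_map):
        members = orders_map[order]
        base_mz = float(rng.uniform(650.0, 980.0))
        deltas = np.sort(rng.uniform(60.0, 320.0, size=7))
        level = float(rng.uniform(2e4, 8e4))
        for k in range(config.n_novel_per_order):
            prec = base_mz + k * config.unknown_analog_shift
            peaks = [(max(prec - d, 50.0), float(rng.uniform(20.0, 90.0)))
                     for d in deltas]
            intens = {
                f"{p.name}_r{r}": level * float(
                    rng.lognormal(0.0, config.tier_sigma)
                )
                for p in members
                for r in range(1, config.n_replicates + 1)
            }
            emit(f"novel:{order}:{k+1}", "[M+H]+", prec, intens, peaks,
                 "novel_family", float(rng.uniform(3.0, 34.0)))

    # ------------------------------------------------------------------
    # Blank contaminants (blank-dominant; filtered by the 10x rule)
    # ------------------------------------------------------------------
    for c in range(config.n_contaminants):
        mz_true = float(rng.uniform(200.0, 900.0))
        level = float(rng.uniform(5e4, 5e5))
        intens = {b: level * float(rng.lognormal(0.0, 0.2)) for b in blanks}
        for sid in samples:  # carry-over below the blank threshold
            intens[sid] = level * float(rng.uniform(0.05, 0.5))
        peaks = sorted(
            (float(rng.uniform(80.0, mz_true - 20.0)),
             float(rng.uniform(5.0, 100.0)))
            for _ in range(6)
        )
        emit(f"contaminant:{c+1}", "[M+H]+", mz_true, intens, peaks,
             "contaminant", float(rng.uniform(1.0, 36.0)))

    # Internal standard: constant spike in every non-blank sample
    is_intens = {sid: 1e6 * float(rng.lognormal(0.0, 0.05)) for sid in samples}
    emit("IS:C19-PC", "[M+H]+", IS_C19PC_MZ, is_intens, None,
         "internal_standard", IS_C19PC_RT)

    # ------------------------------------------------------------------
    # Toy 16S alignment along the order topology
    # ------------------------------------------------------------------
    alignment = _simulate_alignment(profiles, config, rng)

    truth = pd.DataFrame(truth_rows)
    return SimulationResult(
        features=features,
        spectra=spectra,
        metadata=metadata,
        ground_truth=truth,
        alignment=alignment,
        library=library,
        profiles=profiles,
    )


_BASES = np.array(list("ACGT"))


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = rng.random(len(seq)) < p
    if hits.any():
        repl = _BASES[rng.integers(0, 4, size=int(hits.sum()))]
        out[hits] = repl
    return out


def _simulate_alignment(
    profiles: list[StrainProfile], config: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    root = _BASES[rng.integers(0, 4, size=config.alignment_length)]
    orders = sorted({p.order for p in profiles})
    ancestors = {o: _mutate(root, config.p_between_orders, rng) for o in orders}
    out = {}
    for p in profiles:
        leaf = _mutate(ancestors[p.order], config.p_within_order, rng)
        out[p.name] = "".join(leaf)
    return out


def strain_sample_map(metadata: SampleMetadata) -> dict[str, list[str]]:
    """strain -> list of its (non-blank) sample columns."""
    out: dict[str, list[str]] = {}
    for sid, role in metadata.roles.items():
        if role != "sample":
            continue
        out.setdefault(metadata.strains[sid], []).append(sid)
    return out
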