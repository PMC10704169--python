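"""Enumeration of halobacterial lipid species and rule-based MS2 prediction.

The membrane lipids of Halobacteria are built on diether cores (archaeol:
two phytanyl C20 chains ether-linked to glycerol; extended archaeol swaps
one chain for C25) carrying phospho- and/or glycosyl head groups, plus the
non-bilayer lipids menaquinone (MK) and the C50 carotenoid bacterioruberin.
This module enumerates those species combinatorially, computes their
elemental compositions by condensation bookkeeping (one H2O removed per
covalent junction), and predicts MS2 spectra from an editable table of
class-level fragmentation rules, exported as an MSP text library.

Unsaturation is modelled at the composition level only (-H2 per double
bond); positional isomers are not distinguished.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from halolip.composition import (
    CH2,
    H2,
    SO3,
    WATER,
    ADDUCTS,
    ElementComposition,
    adduct_mz,
    monoisotopic_mass,
)

GLYCEROL = ElementComposition(C=3, H=8, O=3)
PHOSPHATE = ElementComposition(H=3, O=4, P=1)  # H3PO4

MAX_UNSATURATION = 8


# ---------------------------------------------------------------------------
# Cores
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CoreLipid:
    """Diether core: two isoprenoid chains ether-linked to glycerol.

    Chains are C20 (phytanyl) or C25 (sesterterpanyl); ``unsat_total`` is
    the total number of C=C double bonds across both chains (0-8).
    """

    chain1_len: int
    chain2_len: int
    unsat_total: int = 0

    def __post_init__(self) -> None:
        for c in (self.chain1_len, self.chain2_len):
            if c not in (20, 25):
                raise ValueError(f"chain length must be 20 or 25, got {c}")
        if not 0 <= self.unsat_total <= MAX_UNSATURATION:
            raise ValueError(f"unsaturation must be 0-{MAX_UNSATURATION}")

    @property
    def label(self) -> str:
        n25 = (self.chain1_len == 25) + (self.chain2_len == 25)
        return {0: "AR", 1: "Ext-AR", 2: "diExt-AR"}[n25]

    @property
    def composition(self) -> ElementComposition:
        comp = GLYCEROL
        for c in (self.chain1_len, self.chain2_len):
            # isoprenoid alcohol CcH(2c+2)O, ether bond condenses out H2O
            comp = comp + ElementComposition(C=c, H=2 * c + 2, O=1) - WATER
        return comp - self.unsat_total * H2

    @property
    def chain_unsats(self) -> tuple[int, int]:
        """Split of total unsaturation over the two chains (chain1 first)."""
        u1 = math.ceil(self.unsat_total / 2)
        return u1, self.unsat_total - u1

    def __str__(self) -> str:
        return f"{self.label}({self.chain1_len}:{self.chain2_len}:{self.unsat_total})"


# ---------------------------------------------------------------------------
# Head groups and classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadGroup:
    """Polar head group described as its free (unattached) molecule.

    ``n_cores`` is 1 for diethers and 2 for cardiolipin-type lipids;
    ``n_junctions`` counts the condensation bonds formed on attachment
    (each removes one H2O from the species composition).
    """

    name: str
    free: ElementComposition
    n_cores: int = 1
    n_junctions: int = 1


_GLY_PG = ElementComposition(C=9, H=19, O=11, P=1)   # PG + hexose - H2O
_PG = ElementComposition(C=3, H=9, O=6, P=1)         # glycerophosphate
_PGP = ElementComposition(C=3, H=10, O=9, P=2)
_MGD = ElementComposition(C=6, H=12, O=6)            # hexose
_DGD = _MGD + _MGD - WATER
_TGD = _DGD + _MGD - WATER
_GLY_AHH = ElementComposition(C=12, H=25, N=1, O=11)  # hexosyl-aminohexanehexaol

HEAD_GROUPS: dict[str, HeadGroup] = {
    "none": HeadGroup("none", ElementComposition(), n_cores=1, n_junctions=0),
    # phospholipids
    "PG": HeadGroup("PG", _PG),
    "Me-PGP": HeadGroup("Me-PGP", _PGP + CH2),
    "PGS": HeadGroup("PGS", _PG + SO3),
    "PA": HeadGroup("PA", PHOSPHATE),
    "PE": HeadGroup("PE", ElementComposition(C=2, H=8, N=1, O=4, P=1)),
    "PI": HeadGroup("PI", ElementComposition(C=6, H=13, O=9, P=1)),
    "Gly-PG": HeadGroup("Gly-PG", _GLY_PG),
    # glycolipids
    "MGD": HeadGroup("MGD", _MGD),
    "DGD": HeadGroup("DGD", _DGD),
    "TGD": HeadGroup("TGD", _TGD),
    "S-MGD": HeadGroup("S-MGD", _MGD + SO3),
    "S-DGD": HeadGroup("S-DGD", _DGD + SO3),
    "2S-DGD": HeadGroup("2S-DGD", _DGD + SO3 + SO3),
    "S-Gly-AHH": HeadGroup("S-Gly-AHH", _GLY_AHH + SO3),
    "2S-Gly-AHH": HeadGroup("2S-Gly-AHH", _GLY_AHH + SO3 + SO3),
    # cardiolipins: two diether cores sharing one head
    "BPG": HeadGroup("BPG", _PGP, n_cores=2, n_junctions=2),
    "MGD-PA": HeadGroup("MGD-PA", _MGD + PHOSPHATE, n_cores=2, n_junctions=3),
    "DGD-PA": HeadGroup("DGD-PA", _DGD + PHOSPHATE, n_cores=2, n_junctions=3),
    "TGD-PA": HeadGroup("TGD-PA", _TGD + PHOSPHATE, n_cores=2, n_junctions=3),
    "S-DGD-PA": HeadGroup("S-DGD-PA", _DGD + SO3 + PHOSPHATE, n_cores=2, n_junctions=3),
}

#: lipid_class -> class group used in summaries; class name equals the head
#: group name for IPLs, "AR" for free cores, "MK"/"BR" for non-bilayer lipids.
CLASS_GROUPS: dict[str, str] = {
    "AR": "core",
    "PG": "phospholipid", "Me-PGP": "phospholipid", "PGS": "phospholipid",
    "PA": "phospholipid", "PE": "phospholipid", "PI": "phospholipid",
    "Gly-PG": "phospholipid",
    "MGD": "glycolipid", "DGD": "glycolipid", "TGD": "glycolipid",
    "S-MGD": "glycolipid", "S-DGD": "glycolipid", "2S-DGD": "glycolipid",
    "S-Gly-AHH": "glycolipid", "2S-Gly-AHH": "glycolipid",
    "BPG": "cardiolipin", "MGD-PA": "cardiolipin", "DGD-PA": "cardiolipin",
    "TGD-PA": "cardiolipin", "S-DGD-PA": "cardiolipin",
    "MK": "quinone",
    "BR": "carotenoid",
}

ALL_CLASSES: tuple[str, ...] = tuple(CLASS_GROUPS)

_MENADIONE = ElementComposition(C=11, H=8, O=2)  # 2-methyl-1,4-naphthoquinone
_BACTERIORUBERIN = ElementComposition(C=50, H=76, O=4)


def menaquinone_composition(n_isoprene: int, n_unsat: int) -> ElementComposition:
    """MK_n:m — polyprenyl chain of n isoprene units with m chain C=C bonds."""
    if not 1 <= n_unsat <= n_isoprene:
        raise ValueError("chain unsaturation must be in 1..n_isoprene")
    chain = ElementComposition(C=5 * n_isoprene, H=10 * n_isoprene + 1)
    # substitute one ring H by the chain, then -H2 per chain double bond
    return _MENADIONE - ElementComposition(H=1) + chain - n_unsat * H2


def bacterioruberin_composition(n_anhydro: int = 0) -> ElementComposition:
    """Bacterioruberin C50H76O4 and its anhydro (dehydration) variants."""
    if not 0 <= n_anhydro <= 3:
        raise ValueError("0-3 anhydro steps supported")
    return _BACTERIORUBERIN - n_anhydro * WATER


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidSpecies:
    """One enumerated lipid: class + core(s) + head, with composition."""

    lipid_class: str
    cores: tuple[CoreLipid, ...]
    head: HeadGroup
    composition: ElementComposition
    name: str

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.composition)

    @property
    def group(self) -> str:
        return CLASS_GROUPS[self.lipid_class]


def make_species(lipid_class: str, cores: Sequence[CoreLipid] | None = None) -> LipidSpecies:
    """Assemble a species of a given class from its core(s)."""
    if lipid_class == "MK":
        raise ValueError("use make_menaquinone for MK species")
    if lipid_class == "BR":
        raise ValueError("use make_bacterioruberin for BR species")
    head = HEAD_GROUPS["none"] if lipid_class == "AR" else HEAD_GROUPS[lipid_class]
    cores = tuple(cores or ())
    if len(cores) != head.n_cores:
        raise ValueError(
            f"{lipid_class} requires {head.n_cores} core(s), got {len(cores)}"
        )
    comp = ElementComposition()
    for core in cores:
        comp = comp + core.composition
    comp = comp + head.free - head.n_junctions * WATER
    core_str = ",".join(str(c) for c in cores)
    name = core_str if lipid_class == "AR" else f"{lipid_class} {core_str}"
    return LipidSpecies(lipid_class, cores, head, comp, name)


def make_menaquinone(n_isoprene: int, n_unsat: int) -> LipidSpecies:
    comp = menaquinone_composition(n_isoprene, n_unsat)
    return LipidSpecies(
        "MK", (), HEAD_GROUPS["none"], comp, f"MK_{n_isoprene}:{n_unsat}"
    )


def make_bacterioruberin(n_anhydro: int = 0) -> LipidSpecies:
    comp = bacterioruberin_composition(n_anhydro)
    prefix = {0: "", 1: "anhydro-", 2: "bisanhydro-", 3: "trisanhydro-"}[n_anhydro]
    return LipidSpecies("BR", (), HEAD_GROUPS["none"], comp, f"{prefix}BR")


# ---------------------------------------------------------------------------
# Library configuration and enumeration
# ---------------------------------------------------------------------------

@dataclass
class LibraryConfig:
    """Which classes, core variants, unsaturation range and adducts to build.

    diExt-AR (two C25 chains) is enumerable but excluded by default because
    it has not been observed in halobacterial cultures. [M+Na]+ spectra are
    predicted only for unsaturated species (the sequential intact-chain-loss
    rule) and are excluded from the default annotation library because
    sodium adducts fragment poorly and risk false annotation.
    """

    classes: tuple[str, ...] = ALL_CLASSES
    chain_variants: tuple[tuple[int, int], ...] = ((20, 20), (20, 25))
    unsat_range: tuple[int, int] = (0, MAX_UNSATURATION)
    adducts: tuple[str, ...] = ("[M+H]+", "[M+NH4]+")
    include_sodium_for_unsaturated: bool = False
    mk_isoprene_units: int = 8
    mk_unsat_range: tuple[int, int] = (1, 8)
    br_anhydro_range: tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("config must list at least one lipid class")
        unknown = set(self.classes) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown lipid classes: {sorted(unknown)}")
        if (25, 25) in self.chain_variants and "AR" in self.classes:
            pass  # explicit opt-in to diExt-AR
        for a in self.adducts:
            if a not in ADDUCTS:
                raise ValueError(f"unsupported adduct: {a}")

    def cores(self) -> list[CoreLipid]:
        lo, hi = self.unsat_range
        out = []
        for c1, c2 in self.chain_variants:
            for u in range(lo, hi + 1):
                out.append(CoreLipid(c1, c2, u))
        return out


def enumerate_library(config: LibraryConfig | None = None) -> list[LipidSpecies]:
    """Enumerate all species allowed by the config, deterministically ordered.

    Order: class (config order), then chain carbons ascending, then
    unsaturation ascending; duplicates on (class, cores, head) are removed.
    """
    config = config or LibraryConfig()
    cores = sorted(
        config.cores(),
        key=lambda c: (c.chain1_len + c.chain2_len, c.chain1_len, c.unsat_total),
    )
    species: list[LipidSpecies] = []
    seen: set[tuple] = set()
    for cls in config.classes:
        if cls == "MK":
            lo, hi = config.mk_unsat_range
            block = [make_menaquinone(config.mk_isoprene_units, m)
                     for m in range(hi, lo - 1, -1)]
        elif cls == "BR":
            lo, hi = config.br_anhydro_range
            block = [make_bacterioruberin(k) for k in range(lo, hi + 1)]
        else:
            n_cores = HEAD_GROUPS["none" if cls == "AR" else cls].n_cores
            if n_cores == 1:
                block = [make_species(cls, [c]) for c in cores]
            else:
                # cardiolipins: two cores; enumerate symmetric pairs of the
                # same variant to keep the library compact (mixed-core
                # cardiolipins are rare and unresolvable at MS1)
                block = [make_species(cls, [c, c]) for c in cores]
        for sp in block:
            # MK/BR variants share (class, cores, head); the name carries
            # their full identity
            key = (sp.lipid_class, sp.cores, sp.head.name, sp.name)
            if key not in seen:
                seen.add(key)
                species.append(sp)
    return species


# ---------------------------------------------------------------------------
# Fragmentation rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentRule:
    """One class-level fragmentation rule.

    ``value`` is a formula (neutral-loss composition or diagnostic-ion
    neutral formula), a literal ``mz:<value>``, or a token: ``HEAD`` /
    ``HEAD_H2O`` (loss of the condensed head group, optionally with an
    extra water), ``DIAG_HEAD`` / ``DIAG_HEAD_H2O`` (protonated head-group
    ion, optionally dehydrated), ``CHAIN`` / ``CHAIN_H2O`` (loss of each
    intact isoprenoid chain as an alkene, optionally with water) and
    ``CHAIN_SEQ`` (sequential losses of both chains, the sodium-adduct
    rule for unsaturated diethers).
    """

    applies_to: str            # lipid class, class group, or "*"
    adduct: str                # adduct string or "*"
    kind: str                  # neutral_loss | diagnostic_ion
    value: str
    label: str
    intensity: float

    def __post_init__(self) -> None:
        if self.kind not in ("neutral_loss", "diagnostic_ion"):
            raise ValueError(f"unknown rule kind: {self.kind}")
        if not 0 < self.intensity <= 100:
            raise ValueError("rule intensity must be in (0, 100]")

    def matches(self, species: LipidSpecies, adduct: str) -> bool:
        if self.adduct not in ("*", adduct):
            return False
        return self.applies_to in ("*", species.lipid_class, species.group)


def default_rules_path() -> Path:
    return Path(str(resources.files("halolip").joinpath("data/fragment_rules.tsv")))


def load_rules(path: str | Path | None = None) -> list[FragmentRule]:
    """Load the fragmentation-rule table (TSV with header)."""
    path = Path(path) if path is not None else default_rules_path()
    rules = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["applies_to", "adduct", "kind", "value", "label", "intensity"]
        if header != expected:
            raise ValueError(f"rule table must have columns {expected}")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, ad, kind, value, label, inten = line.split("\t")
            rules.append(FragmentRule(a, ad, kind, value, label, float(inten)))
    return rules


def _chain_loss_composition(length: int, unsat: int) -> ElementComposition:
    """Intact chain with u double bonds lost as an alkene/polyene CcH(2c-2u)."""
    return ElementComposition(C=length, H=2 * length - 2 * unsat)


# ---------------------------------------------------------------------------
# Spectrum prediction and MSP I/O
# ---------------------------------------------------------------------------

@dataclass
class LibrarySpectrum:
    """Predicted (or imported) MS2 peak list for a species/adduct pair."""

    name: str
    formula: str
    adduct: str
    precursor_mz: float
    peaks: list[tuple[float, float]] = field(default_factory=list)
    species: LipidSpecies | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        if any(mz <= 0 for mz, _ in self.peaks):
            raise ValueError("all peak m/z must be positive")


def _merge_peaks(peaks: list[tuple[float, float]], tol: float = 1e-4) -> list[tuple[float, float]]:
    peaks = sorted(peaks)
    merged: list[tuple[float, float]] = []
    for mz, inten in peaks:
        if merged and mz - merged[-1][0] < tol:
            pmz, pint = merged[-1]
            merged[-1] = (pmz, max(pint, inten))
        else:
            merged.append((mz, inten))
    return merged


def predict_spectrum(
    species: LipidSpecies,
    adduct: str,
    rules: Iterable[FragmentRule],
    convention: str = "proton",
) -> LibrarySpectrum:
    """Predict the MS2 spectrum of a species/adduct pair from the rule table.

    The precursor is always present at relative intensity 100; each
    applicable rule adds neutral-loss or diagnostic-ion peaks. Duplicate
    m/z (within 1e-4 Da) are merged keeping the larger intensity.
    """
    prec = adduct_mz(species.neutral_mass, adduct, convention)
    peaks: list[tuple[float, float]] = [(prec, 100.0)]
    for rule in rules:
        if not rule.matches(species, adduct):
            continue
        for mz, inten in _rule_peaks(rule, species, prec):
            if mz <= 0:
                raise ValueError(
                    f"rule {rule.label!r} yields non-positive m/z for {species.name}"
                )
            if mz < prec:  # fragments must lie below the precursor
                peaks.append((mz, inten))
    return LibrarySpectrum(
        name=f"{species.name}; {adduct}",
        formula=species.composition.formula(),
        adduct=adduct,
        precursor_mz=prec,
        peaks=_merge_peaks(peaks),
        species=species,
    )


def _rule_peaks(
    rule: FragmentRule, species: LipidSpecies, prec: float
) -> list[tuple[float, float]]:
    v = rule.value
    water = monoisotopic_mass(WATER)
    if v in ("HEAD", "HEAD_H2O"):
        if species.head.name == "none":
            return []
        loss = monoisotopic_mass(species.head.free) - water
        if v == "HEAD_H2O":
            loss += water
        return [(prec - loss, rule.intensity)]
    if v in ("DIAG_HEAD", "DIAG_HEAD_H2O"):
        if species.head.name == "none":
            return []
        mz = monoisotopic_mass(species.head.free) + 1.007276
        if v == "DIAG_HEAD_H2O":
            mz -= water
        return [(mz, rule.intensity)]
    if v in ("CHAIN", "CHAIN_H2O"):
        out = []
        for core in species.cores:
            u1, u2 = core.chain_unsats
            for length, u in ((core.chain1_len, u1), (core.chain2_len, u2)):
                loss = monoisotopic_mass(_chain_loss_composition(length, u))
                if v == "CHAIN_H2O":
                    loss += water
                out.append((prec - loss, rule.intensity))
        return out
    if v == "CHAIN_SEQ":
        # sequential intact losses of both (unsaturated) chains
        if not species.cores or species.cores[0].unsat_total == 0:
            return []
        core = species.cores[0]
        u1, u2 = core.chain_unsats
        l1 = monoisotopic_mass(_chain_loss_composition(core.chain1_len, u1))
        l2 = monoisotopic_mass(_chain_loss_composition(core.chain2_len, u2))
        return [(prec - l1, rule.intensity), (prec - l1 - l2, rule.intensity / 2)]
    if v.startswith("mz:"):
        return [(float(v[3:]), rule.intensity)]
    comp = ElementComposition.from_formula(v)
    if rule.kind == "neutral_loss":
        return [(prec - monoisotopic_mass(comp), rule.intensity)]
    # diagnostic ion given as a neutral formula, reported protonated
    return [(monoisotopic_mass(comp) + 1.007276, rule.intensity)]


# ---------------------------------------------------------------------------
# MSP serialization (NIST text dialect)
# ---------------------------------------------------------------------------

def export_msp(library: Sequence[LibrarySpectrum], path: str | Path) -> None:
    """Write spectra as MSP records (NAME/PRECURSORMZ/.../Num Peaks)."""
    if not library:
        raise ValueError("refusing to export an empty library")
    with open(path, "w") as fh:
        for spec in library:
            fh.write(f"NAME: {spec.name}\n")
            fh.write(f"PRECURSORMZ: {spec.precursor_mz:.4f}\n")
            fh.write(f"PRECURSORTYPE: {spec.adduct}\n")
            fh.write(f"FORMULA: {spec.formula}\n")
            fh.write(f"Num Peaks: {len(spec.peaks)}\n")
            for mz, inten in spec.peaks:
                fh.write(f"{mz:.4f}\t{inten:.1f}\n")
            fh.write("\n")


def read_msp(path: str | Path) -> list[LibrarySpectrum]:
    """Read an MSP library written by :func:`export_msp` (or compatible)."""
    spectra: list[LibrarySpectrum] = []
    fields: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_expected = -1

    def flush() -> None:
        nonlocal fields, peaks, n_expected
        if not fields:
            return
        if n_expected >= 0 and len(peaks) != n_expected:
            raise ValueError(
                f"record {fields.get('NAME', '?')!r}: expected {n_expected} "
                f"peaks, found {len(peaks)}"
            )
        spectra.append(
            LibrarySpectrum(
                name=fields.get("NAME", ""),
                formula=fields.get("FORMULA", ""),
                adduct=fields.get("PRECURSORTYPE", ""),
                precursor_mz=float(fields["PRECURSORMZ"]),
                peaks=peaks,
            )
        )
        fields, peaks, n_expected = {}, [], -1

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, val = line.partition(":")
                key = key.strip()
                if key.lower() == "num peaks":
                    n_expected = int(val)
                else:
                    fields[key.upper()] = val.strip()
            else:
                mz, inten = line.replace("\t", " ").split()[:2]
                peaks.append((float(mz), float(inten)))
    flush()
    return spectra


def build_default_library(
    config: LibraryConfig | None = None,
    rules: Sequence[FragmentRule] | None = None,
) -> list[LibrarySpectrum]:
    """Enumerate species and predict one spectrum per species/adduct pair."""
    config = config or LibraryConfig()
    rules = list(rules) if rules is not None else load_rules()
    spectra = []
    for sp in enumerate_library(config):
        for adduct in config.adducts:
            spectra.append(predict_spectrum(sp, adduct, rules))
        if (
            config.include_sodium_for_unsaturated
            and sp.cores
            and sp.cores[0].unsat_total > 0
        ):
            spectra.append(predict_spectrum(sp, "[M+Na]+", rules))
    return spectra
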