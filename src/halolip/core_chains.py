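"""Core-lipid accounting: collapse intact polar lipids onto diether cores.

Every diether-bearing lipid (free archaeol, IPLs, cardiolipins) is mapped
to its core variant(s); cardiolipins contribute both cores at full weight
(chain accounting is per core). Menaquinones and bacterioruberin carry no
isoprenoid-glycerol core and are excluded. From the per-strain core
profile the chain-level statistics follow: the fraction of unsaturated
cores, the fraction of C25 chains among all chains, and the split of
unsaturated cores into low (<4) and poly (>=4) unsaturation.

When di-extended archaeol is absent every molecule carries at most one
C25 chain, so a C25 *chain* fraction f converts to an Ext-AR *molecule*
fraction of exactly 2f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from halolip.lipid_library import CoreLipid, LipidSpecies

POLY_UNSAT_THRESHOLD = 4


@dataclass
class CoreProfile:
    """Per-strain abundance of each core variant, with derived percentages."""

    abundance: dict[CoreLipid, float] = field(default_factory=dict)

    def add(self, core: CoreLipid, amount: float) -> None:
        self.abundance[core] = self.abundance.get(core, 0.0) + amount

    @property
    def total(self) -> float:
        return sum(self.abundance.values())

    @property
    def pct_unsaturated(self) -> float:
        if self.total == 0:
            return 0.0
        uns = sum(a for c, a in self.abundance.items() if c.unsat_total > 0)
        return 100.0 * uns / self.total

    @property
    def pct_c25_chains(self) -> float:
        """C25 chains as a percentage of all isoprenoid chains (2/molecule)."""
        if self.total == 0:
            return 0.0
        c25 = sum(
            a * ((c.chain1_len == 25) + (c.chain2_len == 25))
            for c, a in self.abundance.items()
        )
        return 100.0 * c25 / (2.0 * self.total)

    @property
    def pct_ext_ar(self) -> float:
        if self.total == 0:
            return 0.0
        ext = sum(a for c, a in self.abundance.items() if c.label == "Ext-AR")
        return 100.0 * ext / self.total


def to_core_profile(
    lipids_with_species: Sequence[tuple[LipidSpecies, Mapping[str, float]]],
    strains: Mapping[str, Sequence[str]],
) -> dict[str, CoreProfile]:
    """Aggregate lipid abundances onto cores, per strain.

    ``lipids_with_species`` pairs each species with its per-sample
    abundance; ``strains`` maps strain name -> its sample columns
    (replicates are summed). MK and bacterioruberin are skipped; any other
    species without a core raises.
    """
    profiles: dict[str, CoreProfile] = {s: CoreProfile() for s in strains}
    for species, abundance in lipids_with_species:
        if species.lipid_class in ("MK", "BR"):
            continue
        if not species.cores:
            raise ValueError(
                f"species {species.name!r} has no diether core; cannot "
                "enter core aggregation"
            )
        for strain, samples in strains.items():
            amount = sum(abundance.get(s, 0.0) for s in samples)
            if amount <= 0:
                continue
            for core in species.cores:  # cardiolipins contribute both cores
                profiles[strain].add(core, amount)
    return profiles


def chain_fraction_to_molecule_fraction(f_chain: float) -> float:
    """Convert a C25 chain %% to an Ext-AR molecule %% (no diExt-AR).

    Each molecule holds two chains and at most one may be C25, so the
    molecule-level fraction is exactly twice the chain-level one.
    """
    if not 0.0 <= f_chain <= 50.0:
        raise ValueError(
            "chain fraction above 50% implies molecules with two C25 "
            "chains (diExt-AR), violating the conversion's precondition"
        )
    return 2.0 * f_chain


def molecule_fraction_to_chain_fraction(f_molecule: float) -> float:
    """Inverse of :func:`chain_fraction_to_molecule_fraction`."""
    if not 0.0 <= f_molecule <= 100.0:
        raise ValueError("molecule fraction must be within 0-100%")
    return f_molecule / 2.0


def unsaturation_summary(profile: CoreProfile) -> dict[str, float]:
    """Unsaturation statistics of one strain's core profile.

    ``pct_low`` and ``pct_poly`` partition the *unsaturated* cores by
    degree (<4 vs >=4) and sum to 100 whenever any unsaturated core is
    present; with a fully saturated profile both are reported as 0 and
    ``no_unsaturated`` is flagged.
    """
    total = profile.total
    uns = {c: a for c, a in profile.abundance.items() if c.unsat_total > 0}
    uns_total = sum(uns.values())
    if total == 0 or uns_total == 0:
        return {
            "pct_unsaturated": 0.0, "pct_low": 0.0, "pct_poly": 0.0,
            "no_unsaturated": True,
        }
    poly = sum(a for c, a in uns.items()
               if c.unsat_total >= POLY_UNSAT_THRESHOLD)
    return {
        "pct_unsaturated": 100.0 * uns_total / total,
        "pct_low": 100.0 * (uns_total - poly) / uns_total,
        "pct_poly": 100.0 * poly / uns_total,
        "no_unsaturated": False,
    }


def core_profile_table(profiles: Mapping[str, CoreProfile]) -> pd.DataFrame:
    """Strain x core-variant abundance table (columns sorted by core)."""
    cores = sorted({c for p in profiles.values() for c in p.abundance})
    data = {
        str(c): [p.abundance.get(c, 0.0) for p in profiles.values()]
        for c in cores
    }
    return pd.DataFrame(data, index=list(profiles))


def core_summary_table(profiles: Mapping[str, CoreProfile]) -> pd.DataFrame:
    """Per-strain summary: unsaturation and chain-length percentages."""
    rows = []
    for strain, p in profiles.items():
        s = unsaturation_summary(p)
        rows.append(
            {
                "strain": strain,
                "pct_unsaturated": round(p.pct_unsaturated, 2),
                "pct_low_unsat": round(s["pct_low"], 2),
                "pct_poly_unsat": round(s["pct_poly"], 2),
                "pct_c25_chains": round(p.pct_c25_chains, 2),
                "pct_ext_ar": round(p.pct_ext_ar, 2),
            }
        )
    return pd.DataFrame(rows).set_index("strain")
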