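"""Feature-based molecular networking with the modified cosine score.

Spectra are first cleaned (precursor-proximal fragments discarded, top-k
peaks per sliding m/z window), then compared pairwise with the modified
cosine: fragment pairs may match directly or shifted by the precursor
mass difference, and an optimal one-to-one assignment maximizes the sum
of square-root intensity products. Spectrum pairs with score above the
cosine threshold AND enough matched peaks become edges; the network is
then pruned (blank-involved nodes, low-m/z nodes, small components) and
components are categorized by their majority annotation or dominant
taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from halolip.features_io import Ms2Spectrum


@dataclass
class NetworkConfig:
    """FBMN parameters (defaults: standard GNPS-style settings)."""

    frag_mz_tol: float = 0.05
    precursor_mz_tol: float = 0.05
    topk: int = 6
    topk_window: float = 50.0        # Da; +-window/2 around each peak
    precursor_exclusion: float = 17.0  # Da
    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    min_component_size: int = 4
    min_node_mz: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_cosine <= 1.0:
            raise ValueError("min_cosine must be in (0, 1]")
        for name in ("frag_mz_tol", "precursor_mz_tol", "topk", "topk_window",
                     "precursor_exclusion", "min_matched_peaks",
                     "min_component_size", "min_node_mz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def filter_spectrum(spec: Ms2Spectrum, config: NetworkConfig | None = None) -> Ms2Spectrum:
    """Drop precursor-proximal fragments and keep top-k peaks per window.

    A peak survives iff it lies at least ``precursor_exclusion`` Da from
    the precursor and ranks within the top ``topk`` intensities among all
    peaks within +-``topk_window``/2 Da of itself. Idempotent.
    """
    config = config or NetworkConfig()
    half = config.topk_window / 2.0
    peaks = [
        (mz, i) for mz, i in spec.peaks
        if abs(mz - spec.precursor_mz) >= config.precursor_exclusion
    ]
    kept = []
    for mz, inten in peaks:
        window = [i2 for mz2, i2 in peaks if abs(mz2 - mz) <= half]
        rank = sum(1 for i2 in window if i2 > inten)
        if rank < config.topk:
            kept.append((mz, inten))
    return Ms2Spectrum(
        precursor_mz=spec.precursor_mz,
        rt=spec.rt,
        peaks=kept,
        source=spec.source,
        feature_id=spec.feature_id,
    ) if kept else Ms2Spectrum(spec.precursor_mz, spec.rt, [], spec.source,
                               spec.feature_id)


def modified_cosine(
    spec_a: Ms2Spectrum,
    spec_b: Ms2Spectrum,
    frag_tol: float = 0.05,
) -> tuple[float, int]:
    """GNPS-style modified cosine: (score in [0, 1], matched peak count).

    Peak pairs are eligible if their m/z agree within ``frag_tol`` either
    directly or after shifting spectrum B by the (signed) precursor mass
    difference. An optimal one-to-one assignment over eligible pairs
    maximizes the summed products of square-root intensities; the score
    is that sum normalized by the two spectra's square-root-intensity
    norms, hence symmetric.
    """
    if not spec_a.peaks or not spec_b.peaks:
        return 0.0, 0
    shift = spec_a.precursor_mz - spec_b.precursor_mz
    mza, ia = spec_a.mz_array, np.sqrt(spec_a.intensity_array)
    mzb, ib = spec_b.mz_array, np.sqrt(spec_b.intensity_array)
    n, m = len(mza), len(mzb)
    weight = np.zeros((n, m))
    eligible = np.zeros((n, m), dtype=bool)
    for i in range(n):
        direct = np.abs(mza[i] - mzb) <= frag_tol
        shifted = np.abs(mza[i] - (mzb + shift)) <= frag_tol
        mask = direct | shifted
        eligible[i] = mask
        weight[i, mask] = ia[i] * ib[mask]
    if not eligible.any():
        return 0.0, 0
    # maximize total weight over one-to-one assignments of eligible pairs
    cost = -weight.copy()
    cost[~eligible] = 0.0  # ineligible pairs contribute nothing
    rows, cols = linear_sum_assignment(cost)
    used = [(r, c) for r, c in zip(rows, cols) if eligible[r, c]]
    score = float(sum(weight[r, c] for r, c in used))
    score /= float(np.linalg.norm(ia) * np.linalg.norm(ib))
    return min(score, 1.0), len(used)


@dataclass
class NetworkNode:
    feature_id: str
    precursor_mz: float
    occurrence: dict[str, float] = field(default_factory=dict)  # strain -> signal
    annotation: str | None = None
    lipid_class: str | None = None
    in_blank: bool = False


def build_network(
    spectra: Sequence[Ms2Spectrum],
    config: NetworkConfig | None = None,
    prefiltered: bool = False,
) -> nx.Graph:
    """Link spectrum pairs with cosine > threshold and enough shared peaks.

    Nodes are keyed by feature id (input order is irrelevant: node and
    edge sets are deterministic functions of the spectra). Spectra are
    run through :func:`filter_spectrum` first unless ``prefiltered``.
    """
    config = config or NetworkConfig()
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to build a network")
    specs = list(spectra) if prefiltered else [
        filter_spectrum(s, config) for s in spectra
    ]
    specs.sort(key=lambda s: s.feature_id)
    g = nx.Graph()
    for s in specs:
        g.add_node(s.feature_id, mz=s.precursor_mz)
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            a, b = specs[i], specs[j]
            score, n_matched = modified_cosine(a, b, config.frag_mz_tol)
            if score > config.min_cosine and n_matched >= config.min_matched_peaks:
                g.add_edge(
                    a.feature_id, b.feature_id,
                    cosine=round(score, 4),
                    matched_peaks=n_matched,
                    delta_mz=round(a.precursor_mz - b.precursor_mz, 4),
                )
    return g


def filter_network(
    g: nx.Graph,
    config: NetworkConfig | None = None,
    blank_features: set[str] | None = None,
) -> nx.Graph:
    """Remove blank-involved and low-m/z nodes, then small components.

    Node filters run first, component-size pruning second, so a component
    shrunk below the minimum by node removal is dropped entirely.
    Boundary semantics: m/z exactly at the minimum is kept; components
    exactly at the minimum size are kept.
    """
    config = config or NetworkConfig()
    blank_features = blank_features or set()
    g = g.copy()
    drop = [
        n for n, data in g.nodes(data=True)
        if n in blank_features or data.get("mz", 0.0) < config.min_node_mz
    ]
    g.remove_nodes_from(drop)
    for comp in list(nx.connected_components(g)):
        if len(comp) < config.min_component_size:
            g.remove_nodes_from(comp)
    return g


def annotate_network(
    g: nx.Graph,
    annotations: Mapping[str, tuple[str, str]] | None = None,
    occurrence: Mapping[str, Mapping[str, float]] | None = None,
    taxa: Mapping[str, str] | None = None,
) -> None:
    """Attach annotation / per-strain occurrence / taxon attributes in place.

    ``annotations`` maps feature id -> (species name, lipid class);
    ``occurrence`` maps feature id -> strain -> signal; ``taxa`` maps
    strain -> taxon (e.g. order) label.
    """
    annotations = annotations or {}
    occurrence = occurrence or {}
    taxa = taxa or {}
    for n in g.nodes:
        ann = annotations.get(n)
        g.nodes[n]["annotation"] = ann[0] if ann else ""
        g.nodes[n]["lipid_class"] = ann[1] if ann else ""
        occ = occurrence.get(n, {})
        g.nodes[n]["occurrence"] = dict(occ)
        g.nodes[n]["taxa"] = sorted({taxa.get(s, s) for s, v in occ.items() if v > 0})


def categorize_components(g: nx.Graph) -> dict[frozenset, str]:
    """Label each component by majority lipid class or dominant taxon.

    With any annotated node, the label is the most frequent annotated
    class. Otherwise, if one taxon contributes more than half of all
    node-taxon occurrences, the label is ``"<taxon>-dominant unknown"``;
    failing that, ``"unknown"``. The labels are also written onto the
    nodes as the ``category`` attribute.
    """
    labels: dict[frozenset, str] = {}
    for comp in nx.connected_components(g):
        classes = [
            g.nodes[n].get("lipid_class") for n in comp
            if g.nodes[n].get("lipid_class")
        ]
        if classes:
            counts = sorted(
                ((classes.count(c), c) for c in set(classes)),
                key=lambda t: (-t[0], t[1]),
            )
            label = counts[0][1]
        else:
            taxon_counts: dict[str, int] = {}
            total = 0
            for n in comp:
                for t in g.nodes[n].get("taxa", []):
                    taxon_counts[t] = taxon_counts.get(t, 0) + 1
                    total += 1
            label = "unknown"
            for t, c in sorted(taxon_counts.items()):
                if total and c > total / 2.0:
                    label = f"{t}-dominant unknown"
                    break
        labels[frozenset(comp)] = label
        for n in comp:
            g.nodes[n]["category"] = label
    return labels


def network_summary(g: nx.Graph) -> dict[str, int]:
    """Node counts partitioned by annotation status.

    ``n_analogs``: unannotated nodes sharing a component with annotated
    ones (putative analogs of known lipids); ``n_new``: unannotated nodes
    in all-unknown components (candidate new structures). The partition
    identity n_nodes = n_identified + n_analogs + n_new always holds.
    """
    n_identified = n_analogs = n_new = 0
    for comp in nx.connected_components(g):
        annotated = [n for n in comp if g.nodes[n].get("annotation")]
        unknown = len(comp) - len(annotated)
        n_identified += len(annotated)
        if annotated:
            n_analogs += unknown
        else:
            n_new += unknown
    return {
        "n_nodes": g.number_of_nodes(),
        "n_identified": n_identified,
        "n_unknown": n_analogs + n_new,
        "n_analogs": n_analogs,
        "n_new": n_new,
    }


def export_graphml(g: nx.Graph, path: str) -> None:
    """GraphML export with scalar attributes (occurrence flattened)."""
    out = nx.Graph()
    for n, data in g.nodes(data=True):
        attrs = {
            "mz": float(data.get("mz", 0.0)),
            "annotation": data.get("annotation", "") or "",
            "lipid_class": data.get("lipid_class", "") or "",
            "category": data.get("category", "") or "",
        }
        for strain, v in data.get("occurrence", {}).items():
            attrs[f"occ_{strain}"] = float(v)
        out.add_node(n, **attrs)
    for u, v, data in g.edges(data=True):
        out.add_edge(u, v, **{k: data[k] for k in
                              ("cosine", "matched_peaks", "delta_mz")
                              if k in data})
    nx.write_graphml(out, path)
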