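"""The DDA-assisted DIA stage: cross-mode feature linking and retention.

DDA acquisition yields clean MS2 spectra but covers few precursors; DIA
covers everything but its spectra are chimeric. The strategy implemented
here combines both: (1) build a molecular network from the DDA spectra and
select its well-connected components (more than three nodes and at least
three edges by default); (2) insert the selected DDA features into the DIA
feature table, pairing DDA and DIA features that agree in precursor m/z and
retention time within tolerance; (3) rebuild the network over the merged
table using each feature's own-mode MS2 spectrum, adding explicit
identity ("match") edges for tolerance-paired features; (4) retain only
features with at least one opposite-mode neighbour — ions supported by both
acquisition modes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .models import (Feature, FeatureTable, Mode, MolecularNetwork,
                     RetainedFeature, SimilarityEdge, Spectrum)
from .networking import NetworkConfig, build_network, component_stats
from .similarity import ScoreConfig

log = logging.getLogger(__name__)


@dataclass
class CrossModeConfig:
    """Thresholds of the cross-mode stage.

    Component selection defaults to nodes > 3 (i.e. at least 4) and
    edges >= 3; both comparisons are configurable because the criterion
    "more than three nodes and three edges" is ambiguous. The DDA-DIA match
    tolerances reuse the upstream alignment values (0.01 Da MS1, 0.05 min RT).
    ``cross_witness`` controls which edge kinds count as cross-mode support:
    "any" (similarity or match, default) or "similarity_only".
    """

    min_component_nodes: int = 3
    min_component_edges: int = 3
    nodes_strict: bool = True    # n_nodes > min (default) vs >=
    edges_strict: bool = False   # n_edges >= min (default) vs >
    mz_match_tol: float = 0.01   # Da
    rt_match_tol: float = 0.05   # min
    require_both_modes: bool = True
    cross_witness: str = "any"

    def __post_init__(self) -> None:
        if self.mz_match_tol <= 0 or self.rt_match_tol <= 0:
            raise ValueError("match tolerances must be > 0")
        if self.min_component_nodes < 1 or self.min_component_edges < 1:
            raise ValueError("component minima must be >= 1")
        if self.cross_witness not in ("any", "similarity_only"):
            raise ValueError(f"unknown cross_witness {self.cross_witness!r}")

    def component_passes(self, n_nodes: int, n_edges: int) -> bool:
        nodes_ok = (n_nodes > self.min_component_nodes if self.nodes_strict
                    else n_nodes >= self.min_component_nodes)
        edges_ok = (n_edges > self.min_component_edges if self.edges_strict
                    else n_edges >= self.min_component_edges)
        return nodes_ok and edges_ok


def select_dda_components(net: MolecularNetwork,
                          cfg: CrossModeConfig | None = None) -> set[str]:
    """Union of nodes of DDA-network components clearing the size minima."""
    cfg = cfg or CrossModeConfig()
    stats = component_stats(net)
    selected: set[str] = set()
    for row in stats.itertuples():
        if cfg.component_passes(row.n_nodes, row.n_edges):
            selected |= set(net.components[row.component_id])
    if not selected:
        log.warning("select_dda_components: no component passed "
                    "(nodes %s %d, edges %s %d)",
                    ">" if cfg.nodes_strict else ">=", cfg.min_component_nodes,
                    ">" if cfg.edges_strict else ">=", cfg.min_component_edges)
    return selected


@dataclass
class MatchCandidate:
    dia_id: str
    d_mz: float
    d_rt: float
    distance: float  # sqrt((d_mz/mz_tol)^2 + (d_rt/rt_tol)^2)
    primary: bool = False


@dataclass
class MergeResult:
    """Merged cross-mode feature table plus the DDA-DIA match bookkeeping."""

    table: FeatureTable
    matches: dict[str, list[MatchCandidate]] = field(default_factory=dict)
    renamed: dict[str, str] = field(default_factory=dict)

    def primary_pairs(self) -> list[tuple[str, str]]:
        return [(dda_id, c.dia_id) for dda_id, cands in self.matches.items()
                for c in cands if c.primary]


def merge_into_dia(selected: Sequence[Feature], dia: FeatureTable,
                   cfg: CrossModeConfig | None = None) -> MergeResult:
    """Insert selected DDA features into the DIA table ("new peak table").

    Every DIA feature is kept; every selected DDA feature is inserted and
    annotated with the DIA features agreeing within the m/z and RT
    tolerances. When several DIA features match, all are recorded and the
    one with the smallest normalised distance is flagged primary. DDA
    features without any tolerance match are inserted regardless — they may
    still connect through MS2 similarity downstream. Id collisions between
    the tables are resolved by prefixing the inserted copy with its mode.
    """
    cfg = cfg or CrossModeConfig()
    dia_ids = set(dia.ids())
    merged: list[Feature] = [
        Feature(f.feature_id, f.precursor_mz, f.rt_min, f.height,
                f.spectrum_ref, f.mode or Mode.DIA)
        for f in dia]
    result_matches: dict[str, list[MatchCandidate]] = {}
    renamed: dict[str, str] = {}

    for f in sorted(selected, key=lambda f: f.feature_id):
        new_id = f.feature_id
        if new_id in dia_ids:
            new_id = f"DDA::{f.feature_id}"
            renamed[f.feature_id] = new_id
            log.info("merge_into_dia: id collision, %s inserted as %s",
                     f.feature_id, new_id)
        cands = []
        for g in dia:
            d_mz = f.precursor_mz - g.precursor_mz
            d_rt = f.rt_min - g.rt_min
            if abs(d_mz) <= cfg.mz_match_tol and abs(d_rt) <= cfg.rt_match_tol:
                dist = math.sqrt((d_mz / cfg.mz_match_tol) ** 2 +
                                 (d_rt / cfg.rt_match_tol) ** 2)
                cands.append(MatchCandidate(g.feature_id, d_mz, d_rt, dist))
        if cands:
            cands.sort(key=lambda c: (c.distance, c.dia_id))
            cands[0].primary = True
        result_matches[new_id] = cands
        merged.append(Feature(new_id, f.precursor_mz, f.rt_min, f.height,
                              f.spectrum_ref, f.mode or Mode.DDA))
    return MergeResult(FeatureTable(merged, mode=None),
                       matches=result_matches, renamed=renamed)


def build_cross_network(merged: MergeResult,
                        spectra: Mapping[str, Spectrum],
                        net_cfg: NetworkConfig | None = None,
                        score_cfg: ScoreConfig | None = None,
                        cfg: CrossModeConfig | None = None) -> MolecularNetwork:
    """Molecular network over the merged table, plus DDA-DIA match edges.

    Each feature is represented by its own-mode MS2 spectrum (looked up via
    ``spectrum_ref``); features without MS2 become flagged isolated nodes.
    Tolerance-matched DDA-DIA pairs get additional identity edges of kind
    "match" (score and matched-peak count None; the best match per DDA
    feature is flagged primary), kept distinct from similarity edges in all
    exports.
    """
    net_cfg = net_cfg or NetworkConfig()
    score_cfg = score_cfg or ScoreConfig()
    cfg = cfg or CrossModeConfig()

    keyed: list[Spectrum] = []
    missing: list[Feature] = []
    for f in merged.table:
        ref = f.spectrum_ref
        s = spectra.get(ref) if ref else None
        if s is None or len(s) == 0:
            missing.append(f)
            continue
        # re-key the spectrum under the (possibly re-keyed) feature id and
        # carry the feature's provenance
        keyed.append(Spectrum(f.feature_id, f.precursor_mz, f.rt_min,
                              s.peaks, mode=f.mode))
    if not keyed and not missing:
        raise ValueError("merged table is empty")
    net = build_network(keyed, net_cfg, score_cfg) if keyed else MolecularNetwork()
    for f in missing:
        net.add_node(f.feature_id, f.precursor_mz, f.rt_min, f.mode,
                     has_ms2=False)

    for dda_id, cands in merged.matches.items():
        for c in cands:
            if dda_id not in net.nodes or c.dia_id not in net.nodes:
                continue
            net.add_edge(SimilarityEdge(
                dda_id, c.dia_id, score=None, n_matched=None,
                mass_shift=c.d_mz, kind="match", primary=c.primary))
    net.label_components()
    return net


def retain_cross_mode(net: MolecularNetwork,
                      cfg: CrossModeConfig | None = None) -> list[RetainedFeature]:
    """Keep features with at least one opposite-acquisition-mode neighbour.

    This is the final selection step: in the merged network only ions related
    to both DDA and DIA survive. Returns retained features sorted by
    component id then feature id; also marks ``retained`` on the network's
    nodes.
    """
    cfg = cfg or CrossModeConfig()
    adj = net.adjacency()
    retained: list[RetainedFeature] = []
    for fid, attrs in net.nodes.items():
        mode = attrs["mode"]
        if mode is None:
            continue
        witnesses = set()
        for other, edge in adj[fid]:
            if cfg.cross_witness == "similarity_only" and edge.kind != "similarity":
                continue
            other_mode = net.nodes[other]["mode"]
            if other_mode is not None and other_mode != mode:
                witnesses.add(other)
        if witnesses or not cfg.require_both_modes:
            retained.append(RetainedFeature(
                feature_id=fid, provenance=mode,
                linked_ids=frozenset(witnesses),
                component_id=attrs["component_id"]))
            net.nodes[fid]["retained"] = True
    retained.sort(key=lambda r: (r.component_id, r.feature_id))
    n_dda = sum(1 for r in retained if r.provenance is Mode.DDA)
    log.info("retain_cross_mode: %d retained (%d DDA, %d DIA) of %d nodes",
             len(retained), n_dda, len(retained) - n_dda, net.n_nodes())
    if not retained:
        log.warning("retain_cross_mode: empty retention")
    return retained


def run_crossmode(dda_spectra: Mapping[str, Spectrum],
                  dda_table: FeatureTable,
                  dia_spectra: Mapping[str, Spectrum],
                  dia_table: FeatureTable,
                  net_cfg: NetworkConfig | None = None,
                  score_cfg: ScoreConfig | None = None,
                  cfg: CrossModeConfig | None = None):
    """Full DDA-assisted DIA chain on preprocessed inputs.

    Returns (dda_network, selected_ids, merge_result, cross_network,
    retained). A pure function of its inputs and configuration.
    """
    net_cfg = net_cfg or NetworkConfig()
    score_cfg = score_cfg or ScoreConfig()
    cfg = cfg or CrossModeConfig()

    by_id = dda_table.by_id()
    dda_keyed = []
    for f in dda_table:
        s = dda_spectra.get(f.spectrum_ref) if f.spectrum_ref else None
        if s is not None and len(s) > 0:
            dda_keyed.append(Spectrum(f.feature_id, f.precursor_mz, f.rt_min,
                                      s.peaks, mode=Mode.DDA))
    if not dda_keyed:
        raise ValueError("no DDA features carry MS2 spectra")
    dda_net = build_network(dda_keyed, net_cfg, score_cfg)
    selected_ids = select_dda_components(dda_net, cfg)
    selected = [by_id[i] for i in sorted(selected_ids)]
    merged = merge_into_dia(selected, dia_table, cfg)
    all_spectra = dict(dia_spectra)
    all_spectra.update(dda_spectra)
    cross = build_cross_network(merged, all_spectra, net_cfg, score_cfg, cfg)
    retained = retain_cross_mode(cross, cfg)
    return dda_net, selected_ids, merged, cross, retained
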