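"""Core domain types shared across the pipeline.

The package models an untargeted LC-MS/MS experiment acquired twice over the
same extract: once in data-dependent acquisition (DDA, clean but sparse MS2)
and once in data-independent acquisition (DIA, complete but chimeric MS2).
Everything downstream — filtering, modified-cosine networking, cross-mode
retention, library annotation — operates on the types defined here.

Units: m/z in Da (observed, charge ignored — negative-mode singly-charged
assumption), retention time in minutes, intensities in arbitrary counts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np


class Mode(str, enum.Enum):
    """Acquisition mode of a spectrum or feature."""

    DDA = "DDA"
    DIA = "DIA"

    def __str__(self) -> str:  # plain value in exports
        return self.value

    @property
    def opposite(self) -> "Mode":
        return Mode.DIA if self is Mode.DDA else Mode.DDA


def _coerce_mode(mode: "Mode | str | None") -> Optional[Mode]:
    if mode is None or isinstance(mode, Mode):
        return mode
    return Mode(str(mode).upper())


@dataclass(frozen=True, order=True)
class Peak:
    """A single fragment ion: m/z (Da) and abundance (counts)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


class Spectrum:
    """One MS2 spectrum: precursor, retention time, fragment peak list, mode.

    Peaks are stored sorted strictly ascending by m/z; peaks colliding at the
    exact same m/z are merged by summing their intensities, so downstream
    matching can treat m/z values as distinct keys.
    """

    __slots__ = ("spectrum_id", "precursor_mz", "rt_min", "peaks", "mode",
                 "metadata", "_mz", "_intensity")

    def __init__(
        self,
        spectrum_id: str,
        precursor_mz: float,
        rt_min: float,
        peaks: Iterable[Peak | tuple],
        mode: Mode | str = Mode.DDA,
        metadata: Optional[Mapping] = None,
    ) -> None:
        if not (precursor_mz > 0):
            raise ValueError(f"precursor m/z must be positive, got {precursor_mz}")
        if rt_min < 0:
            raise ValueError(f"retention time must be >= 0 min, got {rt_min}")
        self.spectrum_id = str(spectrum_id)
        self.precursor_mz = float(precursor_mz)
        self.rt_min = float(rt_min)
        self.peaks = _dedupe_sort([p if isinstance(p, Peak) else Peak(*p) for p in peaks])
        self.mode = _coerce_mode(mode)
        self.metadata = dict(metadata or {})
        self._mz: Optional[np.ndarray] = None
        self._intensity: Optional[np.ndarray] = None

    @property
    def mz(self) -> np.ndarray:
        if self._mz is None:
            self._mz = np.array([p.mz for p in self.peaks], dtype=float)
        return self._mz

    @property
    def intensities(self) -> np.ndarray:
        if self._intensity is None:
            self._intensity = np.array([p.intensity for p in self.peaks], dtype=float)
        return self._intensity

    def __len__(self) -> int:
        return len(self.peaks)

    def __repr__(self) -> str:
        return (f"Spectrum({self.spectrum_id!r}, precursor_mz={self.precursor_mz:.4f}, "
                f"rt_min={self.rt_min:.2f}, n_peaks={len(self.peaks)}, mode={self.mode})")

    def replace_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        """Copy of this spectrum with a different peak list."""
        return Spectrum(self.spectrum_id, self.precursor_mz, self.rt_min,
                        peaks, self.mode, self.metadata)


def _dedupe_sort(peaks: list[Peak]) -> list[Peak]:
    merged: dict[float, float] = {}
    for p in peaks:
        merged[p.mz] = merged.get(p.mz, 0.0) + p.intensity
    return [Peak(mz, merged[mz]) for mz in sorted(merged)]


@dataclass
class Feature:
    """An aligned LC-MS feature (a row of an MS-DIAL-style peak table)."""

    feature_id: str
    precursor_mz: float
    rt_min: float
    height: float
    spectrum_ref: Optional[str] = None
    mode: Optional[Mode] = None

    def __post_init__(self) -> None:
        self.feature_id = str(self.feature_id)
        self.precursor_mz = float(self.precursor_mz)
        self.rt_min = float(self.rt_min)
        self.height = float(self.height)
        if self.height < 0:
            raise ValueError(f"feature height must be >= 0, got {self.height}")
        self.mode = _coerce_mode(self.mode)


class FeatureTable:
    """A set of aligned features from one acquisition mode (or a merged set).

    Feature ids are unique within a table; ``mode`` is None for merged
    cross-mode tables, where each feature carries its own provenance.
    """

    def __init__(self, features: Iterable[Feature], mode: Mode | str | None = None):
        self.mode = _coerce_mode(mode)
        self.features: list[Feature] = list(features)
        seen: set[str] = set()
        dupes: list[str] = []
        for f in self.features:
            if f.feature_id in seen:
                dupes.append(f.feature_id)
            seen.add(f.feature_id)
            if f.mode is None:
                f.mode = self.mode
        if dupes:
            raise ValueError(f"duplicate feature ids in table: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self.by_id()[feature_id]

    def by_id(self) -> dict[str, Feature]:
        return {f.feature_id: f for f in self.features}

    def ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def __repr__(self) -> str:
        return f"FeatureTable(mode={self.mode}, n={len(self)})"


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected pairwise relation between two spectra/features.

    ``kind`` is "similarity" for modified-cosine edges (score and matched-peak
    count set) and "match" for precursor/RT identity links between a DDA
    feature and its tolerance-matched DIA feature (score and n_matched None).
    Endpoints are stored canonically with ``id_a < id_b``; ``mass_shift`` is
    precursor_mz(id_a) - precursor_mz(id_b).
    """

    id_a: str
    id_b: str
    score: Optional[float]
    n_matched: Optional[int]
    mass_shift: Optional[float]
    kind: str = "similarity"
    primary: bool = False  # best tolerance match among several (match edges)

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-edge on {self.id_a!r}")
        if self.id_a > self.id_b:
            a, b = self.id_a, self.id_b
            object.__setattr__(self, "id_a", b)
            object.__setattr__(self, "id_b", a)
            if self.mass_shift is not None:
                object.__setattr__(self, "mass_shift", -self.mass_shift)
        if self.score is not None and not (-1e-9 <= self.score <= 1 + 1e-9):
            raise ValueError(f"cosine score outside [0, 1]: {self.score}")
        if self.kind not in ("similarity", "match"):
            raise ValueError(f"unknown edge kind {self.kind!r}")

    def other(self, feature_id: str) -> str:
        if feature_id == self.id_a:
            return self.id_b
        if feature_id == self.id_b:
            return self.id_a
        raise KeyError(feature_id)


class MolecularNetwork:
    """Graph over features with labelled connected components.

    Nodes carry ``precursor_mz``, ``rt_min``, ``mode``, ``component_id`` and
    a ``retained`` flag filled in by the cross-mode stage. Components are the
    connected components of the edge set (similarity and match edges alike),
    labelled 0, 1, ... in order of their smallest member feature id, so the
    labelling is a pure function of the graph.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, dict] = {}
        self.edges: list[SimilarityEdge] = []
        self.components: dict[int, frozenset[str]] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, feature_id: str, precursor_mz: float, rt_min: float,
                 mode: Mode | str | None, **attrs) -> None:
        self.nodes[str(feature_id)] = {
            "precursor_mz": float(precursor_mz),
            "rt_min": float(rt_min),
            "mode": _coerce_mode(mode),
            "component_id": None,
            "retained": False,
            **attrs,
        }

    def add_edge(self, edge: SimilarityEdge) -> None:
        if edge.id_a not in self.nodes or edge.id_b not in self.nodes:
            raise KeyError(f"edge endpoint not in network: {edge.id_a}/{edge.id_b}")
        self.edges.append(edge)

    def label_components(self) -> None:
        """(Re)label connected components deterministically."""
        parent = {n: n for n in self.nodes}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in self.edges:
            ra, rb = find(e.id_a), find(e.id_b)
            if ra != rb:
                parent[ra] = rb
        groups: dict[str, set[str]] = {}
        for n in self.nodes:
            groups.setdefault(find(n), set()).add(n)
        ordered = sorted(groups.values(), key=min)
        self.components = {i: frozenset(g) for i, g in enumerate(ordered)}
        for cid, members in self.components.items():
            for n in members:
                self.nodes[n]["component_id"] = cid

    # -- queries ----------------------------------------------------------
    def neighbors(self, feature_id: str) -> list[tuple[str, SimilarityEdge]]:
        out = []
        for e in self.edges:
            if feature_id in (e.id_a, e.id_b):
                out.append((e.other(feature_id), e))
        return out

    def adjacency(self) -> dict[str, list[tuple[str, SimilarityEdge]]]:
        adj: dict[str, list[tuple[str, SimilarityEdge]]] = {n: [] for n in self.nodes}
        for e in self.edges:
            adj[e.id_a].append((e.id_b, e))
            adj[e.id_b].append((e.id_a, e))
        return adj

    def component_edges(self, component_id: int) -> list[SimilarityEdge]:
        members = self.components[component_id]
        return [e for e in self.edges if e.id_a in members]

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def __repr__(self) -> str:
        return (f"MolecularNetwork(n_nodes={len(self.nodes)}, "
                f"n_edges={len(self.edges)}, n_components={len(self.components)})")


@dataclass
class RetainedFeature:
    """A feature kept by the cross-mode filter, with its witnesses.

    ``linked_ids`` are the opposite-mode neighbours (via similarity or match
    edges) that justify retention.
    """

    feature_id: str
    provenance: Mode
    linked_ids: frozenset[str]
    component_id: int


@dataclass(frozen=True)
class LibraryEntry:
    """One reference compound of an in-house spectral library."""

    name: str
    precursor_mz: float
    peaks: tuple[Peak, ...]
    formula: Optional[str] = None
    compound_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.precursor_mz > 0):
            raise ValueError(f"library precursor m/z must be positive: {self.name}")
        object.__setattr__(self, "peaks", tuple(_dedupe_sort(list(self.peaks))))

    def as_spectrum(self) -> Spectrum:
        return Spectrum(f"lib::{self.name}", self.precursor_mz, 0.0, self.peaks)


@dataclass
class AnnotationHit:
    """A ranked library candidate for one retained feature."""

    feature_id: str
    library_name: str
    precursor_error_da: float
    precursor_error_ppm: float
    ms2_score: Optional[float]
    n_matched: Optional[int]
    rank: int
    ms1_only: bool = False


def ppm_error(observed: float, reference: float) -> float:
    """Mass error in parts per million relative to the reference mass."""
    return (observed - reference) / reference * 1e6


def nearly_equal(a: float, b: float, decimals: int = 6) -> bool:
    return math.isclose(a, b, abs_tol=10 ** -decimals)
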