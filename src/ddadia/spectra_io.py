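"""Readers and writers for the pipeline's external representations.

Supported formats:

* MGF peak lists (``BEGIN IONS``/``END IONS`` blocks) — the exchange format
  produced by MS-DIAL and consumed by GNPS.
* MSP libraries (``Name:`` / ``PrecursorMZ:`` / ``Num Peaks:`` records) — the
  usual dialect for in-house spectral libraries.
* Tab-separated feature tables with configurable column mapping (MS-DIAL
  alignment export style).
* Molecular networks as GraphML (Cytoscape-loadable) or a two-file
  node/edge TSV pair.

The MGF/MSP readers track line numbers so that malformed records can be
reported precisely, and parsers never silently drop data: every rejected row
or record is returned in a rejection report with a reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .models import (Feature, FeatureTable, LibraryEntry, Mode,
                     MolecularNetwork, Peak, SimilarityEdge, Spectrum)

log = logging.getLogger(__name__)

MZ_FMT = "%.6f"          # 1e-6 Da << any tolerance used downstream
INTENSITY_FMT = "%.4f"
RT_FMT = "%.4f"


class ParseError(ValueError):
    """Raised for malformed spectral or tabular input, naming the location."""


@dataclass
class RejectionReport:
    """Rows/records a parser refused, each with a human-readable reason."""

    rejected: list[dict] = field(default_factory=list)

    def add(self, location: str, reason: str, payload: Optional[str] = None) -> None:
        self.rejected.append({"location": location, "reason": reason,
                              "payload": payload})

    def __len__(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path, mode: Mode | str = Mode.DDA,
             default_rt_min: Optional[float] = None) -> list[Spectrum]:
    """Read an MGF peak list into :class:`Spectrum` objects.

    ``PEPMASS`` (first value) becomes the precursor m/z; ``RTINSECONDS`` is
    converted to minutes. A record without retention time is an error unless
    ``default_rt_min`` is given. Peaks are re-sorted ascending by m/z.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    n_blocks = 0
    with path.open() as fh:
        lines = fh.readlines()

    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.upper() == "BEGIN IONS":
            begin_ln = i + 1  # 1-based
            n_blocks += 1
            params: dict[str, str] = {}
            peaks: list[Peak] = []
            i += 1
            while i < len(lines):
                line = lines[i].strip()
                if line.upper() == "END IONS":
                    break
                if not line or line.startswith("#"):
                    i += 1
                    continue
                if "=" in line:
                    key, _, val = line.partition("=")
                    params[key.strip().upper()] = val.strip()
                else:
                    parts = line.split()
                    try:
                        mz, intensity = float(parts[0]), float(parts[1])
                    except (IndexError, ValueError):
                        raise ParseError(
                            f"{path}:{i + 1}: non-numeric peak line {line!r}") from None
                    peaks.append(Peak(mz, intensity))
                i += 1
            else:
                raise ParseError(f"{path}:{begin_ln}: BEGIN IONS without END IONS")
            spectra.append(_mgf_block_to_spectrum(
                params, peaks, path, begin_ln, mode, default_rt_min,
                index=len(spectra)))
        i += 1

    if n_blocks == 0:
        warnings.warn(f"{path}: no BEGIN IONS records found", stacklevel=2)
    return spectra


def _mgf_block_to_spectrum(params, peaks, path, line_no, mode,
                           default_rt_min, index) -> Spectrum:
    if "PEPMASS" not in params:
        raise ParseError(f"{path}:{line_no}: record missing PEPMASS")
    try:
        precursor_mz = float(params["PEPMASS"].split()[0])
    except ValueError:
        raise ParseError(
            f"{path}:{line_no}: non-numeric PEPMASS {params['PEPMASS']!r}") from None

    if "RTINSECONDS" in params:
        rt_min = float(params["RTINSECONDS"]) / 60.0
    elif "RTINMINUTES" in params:
        rt_min = float(params["RTINMINUTES"])
    elif default_rt_min is not None:
        rt_min = default_rt_min
    else:
        raise ParseError(f"{path}:{line_no}: record has no retention time "
                         "(RTINSECONDS) and no default was configured")

    spectrum_id = params.get("TITLE") or params.get("FEATURE_ID") or \
        f"{path.stem}_{index}"
    return Spectrum(spectrum_id, precursor_mz, rt_min, peaks, mode=mode)


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as MGF; retention time is emitted as RTINSECONDS."""
    path = Path(path)
    with path.open("w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={MZ_FMT % s.precursor_mz}\n")
            fh.write(f"RTINSECONDS={RT_FMT % (s.rt_min * 60.0)}\n")
            fh.write(f"MODE={s.mode.value if s.mode else ''}\n")
            for p in s.peaks:
                fh.write(f"{MZ_FMT % p.mz} {INTENSITY_FMT % p.intensity}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# MSP (spectral libraries)
# ---------------------------------------------------------------------------

def read_msp(path) -> list[LibraryEntry]:
    """Read an MSP spectral library (Name:/PrecursorMZ:/Num Peaks: dialect)."""
    path = Path(path)
    entries: list[LibraryEntry] = []
    header: dict[str, str] = {}
    peaks: list[Peak] = []
    start_ln = 1

    def flush(ln: int) -> None:
        if not header and not peaks:
            return
        name = header.get("NAME")
        if name is None:
            raise ParseError(f"{path}:{start_ln}: record missing Name:")
        prec = header.get("PRECURSORMZ") or header.get("PRECURSOR_MZ")
        if prec is None:
            raise ParseError(f"{path}:{start_ln}: record {name!r} missing PrecursorMZ:")
        entries.append(LibraryEntry(
            name=name, precursor_mz=float(prec), peaks=tuple(peaks),
            formula=header.get("FORMULA"),
            compound_class=header.get("COMPOUNDCLASS") or header.get("CLASS")))

    ln = 0
    with path.open() as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush(ln)
                header, peaks = {}, []
                start_ln = ln + 1
                continue
            if ":" in line and not line.split(":", 1)[0].replace(".", "").isdigit():
                key, _, val = line.partition(":")
                header[key.strip().upper().replace(" ", "")] = val.strip()
            else:
                parts = line.replace(";", " ").split()
                try:
                    peaks.append(Peak(float(parts[0]), float(parts[1])))
                except (IndexError, ValueError):
                    raise ParseError(
                        f"{path}:{ln}: non-numeric peak line {line!r}") from None
        flush(ln)
    return entries


def write_msp(entries: Sequence[LibraryEntry], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for e in entries:
            fh.write(f"Name: {e.name}\n")
            fh.write(f"PrecursorMZ: {MZ_FMT % e.precursor_mz}\n")
            if e.formula:
                fh.write(f"Formula: {e.formula}\n")
            if e.compound_class:
                fh.write(f"CompoundClass: {e.compound_class}\n")
            fh.write(f"Num Peaks: {len(e.peaks)}\n")
            for p in e.peaks:
                fh.write(f"{MZ_FMT % p.mz} {INTENSITY_FMT % p.intensity}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

#: default header names, MS-DIAL alignment-export style; first match wins
DEFAULT_COLUMNS = {
    "feature_id": ("feature_id", "Alignment ID", "id", "ID"),
    "precursor_mz": ("precursor_mz", "Average Mz", "mz", "m/z"),
    "rt_min": ("rt_min", "Average Rt(min)", "rt", "RT(min)"),
    "height": ("height", "Height", "Area", "area"),
    "spectrum_ref": ("spectrum_ref", "MS/MS spectrum", "ms2_id"),
}


def read_feature_table(path, mode: Mode | str | None = None,
                       columns: Optional[dict] = None
                       ) -> tuple[FeatureTable, RejectionReport]:
    """Read a tab-separated aligned feature table.

    Returns the parsed table together with a rejection report listing any
    rows that failed numeric parsing. Duplicate feature ids or a missing
    mandatory column raise :class:`ParseError`.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update({k: (v,) if isinstance(v, str) else tuple(v)
                       for k, v in columns.items()})
    df = pd.read_csv(path, sep="\t", dtype=str)

    resolved: dict[str, Optional[str]] = {}
    for field_name, candidates in colmap.items():
        found = next((c for c in candidates if c in df.columns), None)
        if found is None and field_name != "spectrum_ref":
            raise ParseError(f"{path}: missing mandatory column for "
                             f"{field_name!r} (looked for {candidates})")
        resolved[field_name] = found

    report = RejectionReport()
    features: list[Feature] = []
    for row_no, row in df.iterrows():
        raw = {f: (row[c] if c is not None and pd.notna(row[c]) else None)
               for f, c in resolved.items()}
        try:
            features.append(Feature(
                feature_id=raw["feature_id"],
                precursor_mz=float(raw["precursor_mz"]),
                rt_min=float(raw["rt_min"]),
                height=float(raw["height"]),
                spectrum_ref=raw["spectrum_ref"],
                mode=mode,
            ))
        except (TypeError, ValueError) as exc:
            report.add(f"{path}:row {row_no + 2}", str(exc),
                       payload="\t".join("" if pd.isna(v) else str(v) for v in row))

    ids = [f.feature_id for f in features]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ParseError(f"{path}: duplicate feature ids {dupes}")
    return FeatureTable(features, mode=mode), report


def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    rows = [{
        "feature_id": f.feature_id,
        "precursor_mz": MZ_FMT % f.precursor_mz,
        "rt_min": RT_FMT % f.rt_min,
        "height": INTENSITY_FMT % f.height,
        "spectrum_ref": f.spectrum_ref or "",
        "mode": f.mode.value if f.mode else "",
    } for f in table.features]
    pd.DataFrame(rows, columns=["feature_id", "precursor_mz", "rt_min",
                                "height", "spectrum_ref", "mode"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_NODE_ATTRS = ("precursor_mz", "rt_min", "mode", "component_id", "retained")


def network_to_nx(net: MolecularNetwork) -> nx.MultiGraph:
    # a node pair can carry a similarity edge and a match edge in parallel
    g = nx.MultiGraph()
    for fid in sorted(net.nodes):
        attrs = net.nodes[fid]
        g.add_node(fid, **{
            "precursor_mz": attrs["precursor_mz"],
            "rt_min": attrs["rt_min"],
            "mode": attrs["mode"].value if attrs["mode"] else "",
            "component_id": -1 if attrs["component_id"] is None else int(attrs["component_id"]),
            "retained": bool(attrs["retained"]),
        })
    for e in sorted(net.edges, key=lambda e: (e.id_a, e.id_b, e.kind)):
        attrs: dict = {"kind": e.kind, "primary": e.primary}
        if e.score is not None:
            attrs["score"] = float(e.score)
        if e.n_matched is not None:
            attrs["n_matched"] = int(e.n_matched)
        if e.mass_shift is not None:
            attrs["mass_shift"] = float(e.mass_shift)
        g.add_edge(e.id_a, e.id_b, **attrs)
    return g


def nx_to_network(g: nx.Graph | nx.MultiGraph) -> MolecularNetwork:
    net = MolecularNetwork()
    for n, attrs in g.nodes(data=True):
        net.add_node(n, attrs["precursor_mz"], attrs["rt_min"],
                     attrs["mode"] or None)
        net.nodes[n]["retained"] = bool(attrs.get("retained", False))
    for a, b, attrs in g.edges(data=True):
        net.add_edge(SimilarityEdge(
            a, b, score=attrs.get("score"), n_matched=attrs.get("n_matched"),
            mass_shift=attrs.get("mass_shift"), kind=attrs.get("kind", "similarity"),
            primary=bool(attrs.get("primary", False))))
    net.label_components()
    return net


def write_network(net: MolecularNetwork, path, format: str = "graphml") -> None:
    """Export a finalized network as GraphML or a node/edge TSV pair.

    GraphML output loads directly into Cytoscape. ``edge_tsv`` writes
    ``<path>.nodes.tsv`` and ``<path>.edges.tsv``.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network_to_nx(net), path)
    elif format == "edge_tsv":
        nodes = pd.DataFrame([{
            "feature_id": fid,
            "precursor_mz": MZ_FMT % a["precursor_mz"],
            "rt_min": RT_FMT % a["rt_min"],
            "mode": a["mode"].value if a["mode"] else "",
            "component_id": -1 if a["component_id"] is None else a["component_id"],
            "retained": a["retained"],
        } for fid, a in sorted(net.nodes.items())])
        edges = pd.DataFrame([{
            "id_a": e.id_a, "id_b": e.id_b,
            "score": "" if e.score is None else "%.6f" % e.score,
            "n_matched": "" if e.n_matched is None else e.n_matched,
            "mass_shift": "" if e.mass_shift is None else MZ_FMT % e.mass_shift,
            "kind": e.kind, "primary": e.primary,
        } for e in sorted(net.edges, key=lambda e: (e.id_a, e.id_b, e.kind))])
        nodes.to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False)
        edges.to_csv(path.with_suffix(path.suffix + ".edges.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> MolecularNetwork:
    """Read a GraphML export back into a :class:`MolecularNetwork`."""
    return nx_to_network(nx.read_graphml(Path(path)))
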